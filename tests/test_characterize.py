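"""Random-barcode characterization, curve refitting, and set comparison."""

import numpy as np
import pytest

from barcodeopt import characterize as chz
from barcodeopt import optimizer as opt
from barcodeopt import penalties as pen


@pytest.fixture(scope="module")
def random_summary():
    return chz.characterize_random(
        l=12, n_barcodes=20_000, pair_sample=200_000, cp_pair_sample=50_000, seed=8
    )


class TestCharacterizeRandom:
    def test_bit_reproducible(self):
        kw = dict(l=10, n_barcodes=2_000, pair_sample=20_000, seed=5)
        a = chz.characterize_random(**kw)
        b = chz.characterize_random(**kw)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)
            np.testing.assert_array_equal(a[name].counts, b[name].counts)

    def test_gcc_centered_at_50(self, random_summary):
        s = random_summary["gcc"]
        assert s.mode == pytest.approx(50.0)
        assert s.mean == pytest.approx(50.0, abs=1.0)

    def test_hd_mode_near_three_quarters_l(self, random_summary):
        assert random_summary["hd"].mode == 9
        assert random_summary["hd"].mean == pytest.approx(0.75 * 12, abs=0.05 * 12)

    def test_cp_mode_near_third_of_l(self, random_summary):
        assert random_summary["cp"].mode == 4

    def test_hp_sr_modal_bucket_is_two(self, random_summary):
        assert random_summary["hp"].mode == 2
        assert random_summary["sr"].mode == 2

    def test_histogram_counts_sum_to_items(self, random_summary):
        s = random_summary["gcc"]
        assert s.counts.sum() == s.n_items * s.n_sets

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            chz.characterize_random(l=3, n_barcodes=100, pair_sample=10)

    @pytest.mark.parametrize("l, hd_mode", [(8, 6), (10, 8)])
    def test_hd_mode_scales_with_length(self, l, hd_mode):
        s = chz.characterize_random(
            l=l, n_barcodes=5_000, pair_sample=200_000, cp_pair_sample=1_000, seed=l
        )
        assert s["hd"].mode == hd_mode


class TestFitPenaltyCurves:
    def test_fit_recovers_synthetic_exponential(self):
        # histogram generated exactly from the hp model curve
        x = np.arange(2, 9)
        b, c = 461428.0, -1.31322
        counts = b * np.exp(c * x)
        summary = chz.DistributionSummary(
            factor="hp", values=x, counts=counts, l=12, n_items=int(counts.sum())
        )
        fit = chz.fit_penalty_curves({"hp": summary})["hp"]
        assert fit[0] == pytest.approx(b, rel=1e-3)
        assert fit[1] == pytest.approx(c, rel=1e-3)

    def test_fit_recovers_synthetic_gaussian(self):
        x = np.linspace(0, 100, 13)
        a, mu, sigma = 22662.54, 50.0, 14.74996
        counts = a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
        summary = chz.DistributionSummary(
            factor="gcc", values=x, counts=counts, l=12, n_items=1
        )
        fit = chz.fit_penalty_curves({"gcc": summary})["gcc"]
        assert fit[0] == pytest.approx(a, rel=1e-3)
        assert fit[1] == pytest.approx(mu, abs=1e-3)
        assert abs(fit[2]) == pytest.approx(sigma, rel=1e-3)

    def test_refit_on_fresh_random_data(self):
        summaries = chz.characterize_random(
            l=12, n_barcodes=50_000, n_sets=4, pair_sample=1_000,
            cp_pair_sample=1_000, seed=12,
        )
        fit = chz.fit_penalty_curves(summaries)
        a, mu, sigma = fit["gcc"]
        assert mu == pytest.approx(50.0, abs=1.0)
        assert abs(sigma) == pytest.approx(14.75, abs=0.5)

    def test_degenerate_histogram_rejected(self):
        summary = chz.DistributionSummary(
            factor="gcc", values=np.array([50.0]), counts=np.array([10.0]),
            l=12, n_items=10,
        )
        with pytest.raises(ValueError):
            chz.fit_penalty_curves({"gcc": summary})


class TestCalibration:
    def test_final_weights_beat_unit_weights(self):
        # restricted two-point comparison: the published optimum vs the origin
        base = opt.OptimizerConfig(l=12, n=500, seed=17)
        final = chz.grid_search_weights(base, axes=[[20], [20], [20], [1], [1]], runs=10)
        origin = chz.grid_search_weights(base, axes=[[1], [1], [1], [1], [1]], runs=10)
        assert final.loc[0, "median_p_dec"] >= origin.loc[0, "median_p_dec"]

    def test_single_point_grid(self):
        base = opt.OptimizerConfig(l=12, n=100, seed=1, max_cycles=5)
        table = chz.grid_search_weights(base, axes=[[20], [20], [20], [1], [1]], runs=1)
        assert len(table) == 1

    def test_alpha_sweep_structure_and_determinism(self):
        base = opt.OptimizerConfig(l=12, n=150, seed=9, max_cycles=8)
        alphas = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
        t1 = chz.alpha_sweep(base, alphas=alphas, runs=2)
        t2 = chz.alpha_sweep(base, alphas=alphas, runs=2)
        assert len(t1) == 6
        assert (t1["min_p_wtb"] <= t1["median_p_wtb"]).all()
        np.testing.assert_array_equal(t1.values, t2.values)


class TestCompareSets:
    def test_self_comparison_identical(self, random_seqs):
        seqs = random_seqs(300, 12)
        report = chz.compare_sets(seqs, seqs, pair_sample=5_000, seed=2)
        for fac, sa in report.summaries_a.items():
            sb = report.summaries_b[fac]
            np.testing.assert_array_equal(sa.values, sb.values)
            np.testing.assert_array_equal(sa.counts, sb.counts)

    def test_mixed_lengths_rejected(self, random_seqs):
        with pytest.raises(ValueError, match="length"):
            chz.compare_sets(random_seqs(10, 8), random_seqs(10, 12))

    def test_optimized_set_beats_random(self):
        cfg = opt.OptimizerConfig(l=12, n=1000, seed=31, max_cycles=25)
        initial = {}

        def grab(cycle, state, totals):
            if cycle == 0:
                initial["codes"] = state.codes.copy()

        best, trace = opt.optimize(cfg, callback=grab)
        report = chz.compare_sets(
            initial["codes"], best.codes, pair_sample=50_000, seed=1,
            names=("random", "optimized"),
        )

        def frac_le(summary, cut):
            mask = summary.values <= cut
            return summary.counts[mask].sum() / summary.counts.sum()

        # the heavily penalized hd = 1 pairs are purged
        assert frac_le(report.summaries_b["hd"], 1) <= frac_le(report.summaries_a["hd"], 1)
        hp_a, hp_b = report.summaries_a["hp"], report.summaries_b["hp"]
        frac_ge4 = lambda s: s.counts[s.values >= 4].sum() / s.counts.sum()
        assert frac_ge4(hp_b) < frac_ge4(hp_a)
        # lower median GCC penalty in the optimized set
        gcc_pen_a = pen.p_gcc(np.repeat(report.summaries_a["gcc"].values,
                                        report.summaries_a["gcc"].counts.astype(int)))
        gcc_pen_b = pen.p_gcc(np.repeat(report.summaries_b["gcc"].values,
                                        report.summaries_b["gcc"].counts.astype(int)))
        assert np.mean(gcc_pen_b) < np.mean(gcc_pen_a)

    def test_tsv_roundtrip(self, random_seqs, tmp_path):
        import pandas as pd

        report = chz.compare_sets(
            random_seqs(50, 8), random_seqs(50, 8), pair_sample=500, seed=0
        )
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert set(df.columns) == {"set", "factor", "value", "count"}
        assert set(df["factor"]) >= {"gcc", "hp", "sr", "hd", "ld", "cp"}
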