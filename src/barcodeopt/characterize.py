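"""Random-barcode characterization and calibration experiments.

The penalty curves in :mod:`barcodeopt.penalties` were calibrated against
the factor distributions of uniformly random barcodes. This module
regenerates those distributions at configurable scale, refits the curves,
and runs the weight-grid and alpha-sweep calibration experiments and the
six-criteria comparison between barcode sets (the five factors plus
Levenshtein distance).

For uniform random sequences the reference expectations are simple: GC
content is binomial around 50%, pairwise Hamming distance is binomial with
mean 0.75*l (mode 9 at l = 12), and complementarity peaks near l/3 (mode 4
at l = 12).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import factors, penalties
from .optimizer import OptimizerConfig, optimize

__all__ = [
    "ComparisonReport",
    "DistributionSummary",
    "alpha_sweep",
    "characterize_random",
    "characterize_set",
    "compare_sets",
    "fit_penalty_curves",
    "grid_search_weights",
]

PAIR_FACTORS = ("hd", "cp", "ld")
ALL_FACTORS = ("gcc", "hp", "sr", "hd", "ld", "cp")


@dataclass
class DistributionSummary:
    """Histogram and summary statistics of one factor over a barcode sample."""

    factor: str
    values: np.ndarray               # sorted distinct factor values
    counts: np.ndarray               # total counts over all sets
    l: int
    n_items: int                     # barcodes (or sampled pairs) per set
    n_sets: int = 1
    seed: int | None = None
    per_set_counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def mode(self):
        """Value with maximal count; ties break toward the smaller value."""
        return self.values[int(np.argmax(self.counts))]

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.counts))

    @property
    def median(self) -> float:
        order = np.argsort(self.values)
        cum = np.cumsum(self.counts[order])
        return float(self.values[order][np.searchsorted(cum, cum[-1] / 2.0)])

    def mean_counts(self) -> np.ndarray:
        """Mean count per value across sets (used for the GCC curve fit)."""
        if self.per_set_counts is None:
            return self.counts.astype(float)
        return self.per_set_counts.mean(axis=0)

    def median_counts(self) -> np.ndarray:
        """Median count per value across sets (used for HP/SR curve fits)."""
        if self.per_set_counts is None:
            return self.counts.astype(float)
        return np.median(self.per_set_counts, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "count": self.counts})


def _histogram(values_per_set: Sequence[np.ndarray], factor, l, n_items, seed) -> DistributionSummary:
    all_vals = np.unique(np.concatenate(values_per_set))
    per_set = np.zeros((len(values_per_set), len(all_vals)))
    for i, v in enumerate(values_per_set):
        u, c = np.unique(v, return_counts=True)
        per_set[i, np.searchsorted(all_vals, u)] = c
    return DistributionSummary(
        factor=factor,
        values=all_vals,
        counts=per_set.sum(axis=0),
        l=l,
        n_items=n_items,
        n_sets=len(values_per_set),
        seed=seed,
        per_set_counts=per_set,
    )


def _sample_pair_indices(rng: np.random.Generator, n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """m unordered pairs (i != j) drawn uniformly with replacement."""
    i = rng.integers(0, n, size=m)
    j = rng.integers(0, n - 1, size=m)
    j = np.where(j >= i, j + 1, j)
    return i, j


def _pair_values(
    codes: np.ndarray,
    rng: np.random.Generator,
    pair_sample: int,
    which: Sequence[str],
    min_overlap: int = 3,
) -> dict[str, np.ndarray]:
    """Factor values on a uniform random sample of unordered pairs."""
    n, l = codes.shape
    i, j = _sample_pair_indices(rng, n, pair_sample)
    out: dict[str, np.ndarray] = {}
    packed = factors.pack(codes)
    if "hd" in which:
        y = packed[i] ^ packed[j]
        mism = (y | (y >> np.uint64(1))) & factors._lowbit_mask(l)
        out["hd"] = np.bitwise_count(mism).astype(np.int64)
    if "cp" in which:
        rc = factors.pack(3 - codes[:, ::-1])
        out["cp"] = _cp_elementwise(packed[i], rc[j], l, min_overlap)
    if "ld" in which:
        seqs = factors.decode(codes)
        out["ld"] = np.array(
            [factors.levenshtein(seqs[a], seqs[b]) for a, b in zip(i, j)], dtype=np.int64
        )
    return out


def _cp_elementwise(pa: np.ndarray, prc: np.ndarray, l: int, min_overlap: int) -> np.ndarray:
    """Elementwise complementarity of paired packed arrays (same shape)."""
    mask01 = factors._lowbit_mask(l)
    best = np.zeros(pa.shape, dtype=np.int64)
    for s in range(0, l - min_overlap + 1):
        sh = np.uint64(2 * s)
        valid = np.uint64((int(mask01) >> (2 * s)) << (2 * s))
        for x, y in ((pa, prc), (prc, pa)) if s else ((pa, prc),):
            d = x ^ (y << sh)
            mism = (d | (d >> np.uint64(1))) & valid
            np.maximum(best, (l - s) - np.bitwise_count(mism).astype(np.int64), out=best)
    return best


def characterize_random(
    l: int = 12,
    n_barcodes: int = 10_000,
    n_sets: int = 1,
    pair_sample: int = 1_000_000,
    seed: int | None = None,
    cp_pair_sample: int | None = None,
    ld_pair_sample: int | None = None,
    min_overlap: int = 3,
    include_ld: bool = False,
) -> dict[str, DistributionSummary]:
    """Factor distributions of uniformly random barcode sets.

    Per-barcode factors (gcc, hp, sr) are computed for every barcode of every
    set; pairwise factors on a uniform random sample of unordered pairs
    (``pair_sample`` for hd, ``cp_pair_sample`` for cp — default
    ``pair_sample // 10`` since the sliding-window kernel is costlier).
    Deterministic given ``seed``.
    """
    if n_barcodes > 4**l:
        raise ValueError("n_barcodes exceeds the barcode space")
    cp_pair_sample = pair_sample // 10 if cp_pair_sample is None else cp_pair_sample
    ld_pair_sample = cp_pair_sample if ld_pair_sample is None else ld_pair_sample
    rng = np.random.default_rng(seed)
    per_factor: dict[str, list[np.ndarray]] = {f: [] for f in ALL_FACTORS}
    for _ in range(n_sets):
        codes = rng.integers(0, 4, size=(n_barcodes, l), dtype=np.uint8)
        per_factor["gcc"].append(factors.gc_content_array(codes))
        # hp/sr below 2 share the bottom bucket: penalties treat 1 and 2 alike
        per_factor["hp"].append(np.maximum(factors.homopolymer_length_array(codes), 2))
        per_factor["sr"].append(np.maximum(factors.ssr_repeats_array(codes), 2))
        pv = _pair_values(codes, rng, pair_sample, ("hd",), min_overlap)
        per_factor["hd"].append(pv["hd"])
        per_factor["cp"].append(
            _pair_values(codes, rng, cp_pair_sample, ("cp",), min_overlap)["cp"]
        )
        if include_ld:
            per_factor["ld"].append(
                _pair_values(codes, rng, ld_pair_sample, ("ld",), min_overlap)["ld"]
            )
    out = {}
    for name, chunks in per_factor.items():
        if not chunks:
            continue
        n_items = len(chunks[0])
        out[name] = _histogram(chunks, name, l, n_items, seed)
    return out


def characterize_set(
    barcodes: Sequence[str] | np.ndarray,
    pair_sample: int = 100_000,
    seed: int | None = None,
    min_overlap: int = 3,
) -> dict[str, DistributionSummary]:
    """Six-criteria factor distributions of an explicit barcode set."""
    codes = barcodes if isinstance(barcodes, np.ndarray) else factors.encode(barcodes)
    n, l = codes.shape
    rng = np.random.default_rng(seed)
    pair_sample = min(pair_sample, n * (n - 1) // 2) if n > 1 else 0
    out = {
        "gcc": _histogram([factors.gc_content_array(codes)], "gcc", l, n, seed),
        "hp": _histogram([np.maximum(factors.homopolymer_length_array(codes), 2)], "hp", l, n, seed),
        "sr": _histogram([np.maximum(factors.ssr_repeats_array(codes), 2)], "sr", l, n, seed),
    }
    if pair_sample:
        pv = _pair_values(codes, rng, pair_sample, ("hd", "cp", "ld"), min_overlap)
        for name in ("hd", "cp", "ld"):
            out[name] = _histogram([pv[name]], name, l, pair_sample, seed)
    return out


# ---------------------------------------------------------------------------
# curve refitting
# ---------------------------------------------------------------------------

def _gaussian(x, a, b, c):
    return a * np.exp(-((x - b) ** 2) / (2.0 * c**2))

def _exponential(x, b, c):
    return b * np.exp(c * x)


def fit_penalty_curves(
    summaries: Mapping[str, DistributionSummary],
) -> dict[str, tuple[float, ...]]:
    """Refit the penalty curve shapes from factor distributions.

    The GC-content distribution (mean counts per value across sets) is fit
    with a Gaussian a*exp(-(x-b)^2/(2c^2)); the hp and sr distributions
    (median counts per value, restricted to values >= 2) with a two-parameter
    exponential b*exp(c*x). Returns {"gcc": (a, b, c), "hp": (b, c),
    "sr": (b, c)}. Intended for re-derivation studies; default scoring uses
    the stored constants.
    """
    out: dict[str, tuple[float, ...]] = {}
    if "gcc" in summaries:
        s = summaries["gcc"]
        y = s.mean_counts()
        if len(s.values) < 3:
            raise ValueError("gcc histogram has too few points for a Gaussian fit")
        popt, _ = curve_fit(
            _gaussian, s.values.astype(float), y,
            p0=(float(y.max()), 50.0, 15.0), maxfev=20_000,
        )
        out["gcc"] = tuple(popt)
    for name in ("hp", "sr"):
        if name not in summaries:
            continue
        s = summaries[name]
        keep = s.values >= 2
        x = s.values[keep].astype(float)
        y = s.median_counts()[keep]
        if len(x) < 2:
            raise ValueError(f"{name} histogram has too few points for an exponential fit")
        pos = y > 0
        slope, inter = np.polyfit(x[pos], np.log(y[pos]), 1)
        popt, _ = curve_fit(
            _exponential, x, y, p0=(float(np.exp(inter)), float(slope)), maxfev=20_000
        )
        out[name] = tuple(popt)
    return out


# ---------------------------------------------------------------------------
# calibration experiments
# ---------------------------------------------------------------------------

def grid_search_weights(
    base_cfg: OptimizerConfig,
    grid: Sequence[float] = (1, 5, 10, 20),
    axes: Sequence[Sequence[float]] | None = None,
    runs: int = 3,
) -> pd.DataFrame:
    """Median P_DEC of the objective over a grid of weight vectors.

    ``axes`` gives explicit per-axis values (default: ``grid`` on every
    axis, the full grid**5 lattice). Each point runs the optimizer ``runs``
    times with seeds derived from ``base_cfg.seed``. The returned frame is
    sorted so the best (highest median P_DEC) vector comes first.
    """
    from dataclasses import replace

    axes = [list(grid)] * 5 if axes is None else [list(a) for a in axes]
    rows = []
    ss = np.random.SeedSequence(base_cfg.seed)
    for point in itertools.product(*axes):
        w = penalties.Weights(*point)
        decs = []
        for child in ss.spawn(runs):
            seed = int(child.generate_state(1)[0] % (2**31))
            cfg = replace(base_cfg, weights=w, seed=seed)
            _, trace = optimize(cfg)
            decs.append(trace.p_dec)
        rows.append(
            {"w1": point[0], "w2": point[1], "w3": point[2], "w4": point[3],
             "w5": point[4], "median_p_dec": float(np.median(decs)), "runs": runs}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("median_p_dec", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def alpha_sweep(
    base_cfg: OptimizerConfig,
    alphas: Sequence[float] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50),
    runs: int = 3,
) -> pd.DataFrame:
    """Best and median final objective P_WTb for a range of alpha values."""
    from dataclasses import replace

    rows = []
    ss = np.random.SeedSequence(base_cfg.seed)
    for alpha in alphas:
        pwtbs, decs = [], []
        for child in ss.spawn(runs):
            seed = int(child.generate_state(1)[0] % (2**31))
            cfg = replace(base_cfg, alpha=alpha, seed=seed)
            _, trace = optimize(cfg)
            pwtbs.append(trace.p_wtb)
            decs.append(trace.p_dec)
        rows.append(
            {"alpha": alpha, "min_p_wtb": float(np.min(pwtbs)),
             "median_p_wtb": float(np.median(pwtbs)),
             "median_p_dec": float(np.median(decs)), "runs": runs}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# set comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Six-criteria comparison (gcc, hp, sr, hd, ld, cp) of two barcode sets."""

    name_a: str
    name_b: str
    summaries_a: dict[str, DistributionSummary]
    summaries_b: dict[str, DistributionSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, summaries in ((self.name_a, self.summaries_a), (self.name_b, self.summaries_b)):
            for fac in ALL_FACTORS:
                if fac not in summaries:
                    continue
                s = summaries[fac]
                for v, c in zip(s.values, s.counts):
                    rows.append({"set": name, "factor": fac, "value": v, "count": int(c)})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compare_sets(
    set_a: Sequence[str] | np.ndarray,
    set_b: Sequence[str] | np.ndarray,
    pair_sample: int = 100_000,
    seed: int | None = None,
    min_overlap: int = 3,
    names: tuple[str, str] = ("set_a", "set_b"),
) -> ComparisonReport:
    """Compare two equal-length barcode sets under identical sampling."""
    codes_a = set_a if isinstance(set_a, np.ndarray) else factors.encode(set_a)
    codes_b = set_b if isinstance(set_b, np.ndarray) else factors.encode(set_b)
    if codes_a.shape[1] != codes_b.shape[1]:
        raise ValueError(
            f"sets have different barcode lengths: {codes_a.shape[1]} vs {codes_b.shape[1]}"
        )
    return ComparisonReport(
        names[0],
        names[1],
        characterize_set(codes_a, pair_sample, seed, min_overlap),
        characterize_set(codes_b, pair_sample, seed, min_overlap),
    )
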