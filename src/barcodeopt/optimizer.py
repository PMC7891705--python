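"""Stochastic exclude-and-replace optimization of a barcode set.

The algorithm has two steps: (i) draw an initial set of N distinct uniform
random barcodes of length l; (ii) iterate cycles in which every barcode is
excluded with probability

    P_EX,i = clip(P_Ti / P_WT * N * alpha, 0, 1)

(its share of the weighted objective, scaled so the expected number of
exclusions is N*alpha) and excluded barcodes are replaced with fresh random
barcodes distinct from the survivors. The weighted total P_WT of the best
set seen so far is tracked; the run stops once `patience` consecutive
cycles fail to improve it (or at `max_cycles`, or when P_WT hits 0). The
returned set is the arg-min over all cycles, not the last one.

Because penalty mass concentrates on a minority of bad barcodes (extreme GC,
long homopolymers, close or complementary pairs), high-penalty barcodes are
almost surely replaced each cycle while zero-penalty barcodes are never
touched, and the objective decreases rapidly without getting trapped by the
initial state.

A single seeded :class:`numpy.random.Generator` drives the initial set, the
exclusion draws, and the replacements, in that order, so runs are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import factors, penalties
from .penalties import PenaltyParams, SetTotals, Weights

__all__ = [
    "OptimizerConfig",
    "SetState",
    "Trace",
    "exclusion_probabilities",
    "generate_random_set",
    "optimize",
    "percent_decrease",
    "run_cycle",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters of the set optimizer."""

    l: int = 12
    n: int = 100_000
    alpha: float = 0.2
    weights: Weights = field(default_factory=Weights)
    params: PenaltyParams = field(default_factory=PenaltyParams)
    seed: int | None = None
    patience: int = 5
    max_cycles: int = 200
    min_overlap: int = 3

    def validate(self) -> "OptimizerConfig":
        if self.l < 4:
            raise ValueError("optimizer requires barcode length l >= 4")
        if self.n < 1:
            raise ValueError("set size must be positive")
        if self.n > 4**self.l:
            raise ValueError(f"cannot draw {self.n} distinct barcodes of length {self.l}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        return self


@dataclass
class SetState:
    """A barcode set with its per-barcode penalty components.

    ``components`` holds the unweighted factor penalties (GCC, HP, SR, HD,
    CP) per barcode; pairwise columns are each barcode's summed pair scores
    over its N-1 partners.
    """

    codes: np.ndarray            # (n, l) uint8
    components: np.ndarray       # (n, 5) float

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def l(self) -> int:
        return self.codes.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return factors.decode(self.codes)

    def per_barcode_totals(self, weights: Weights) -> np.ndarray:
        return self.components @ weights.as_array()

    def totals(self, weights: Weights) -> SetTotals:
        return penalties.set_totals(self.components, weights)

    def copy(self) -> "SetState":
        return SetState(self.codes.copy(), self.components.copy())


def compute_state(
    codes: np.ndarray,
    params: PenaltyParams = penalties.DEFAULT_PARAMS,
    min_overlap: int = 3,
) -> SetState:
    """Score a barcode set from scratch (full O(N^2) pairwise recompute)."""
    codes = np.atleast_2d(np.asarray(codes, dtype=np.uint8))
    return SetState(codes, penalties.component_matrix(codes, params, min_overlap))


def _draw_distinct(
    rng: np.random.Generator, l: int, count: int, taken: set[int]
) -> np.ndarray:
    """Draw `count` uniform random l-mers whose packed keys avoid `taken`."""
    space = 4**l
    if len(taken) + count > space:
        raise ValueError(f"cannot draw {count} new distinct barcodes of length {l}")
    if len(taken) + count > space // 2 and space <= 4**10:
        # dense regime: enumerate the space and sample without replacement
        free = np.setdiff1d(np.arange(space, dtype=np.int64), np.fromiter(taken, np.int64, len(taken)))
        picked = rng.choice(free, size=count, replace=False)
        out = np.empty((count, l), dtype=np.uint8)
        for j in range(l):
            out[:, j] = (picked >> (2 * (l - 1 - j))) & 3
        taken.update(int(k) for k in picked)
        return out
    if len(taken) + count > space // 2:
        raise ValueError(
            f"requested density ({len(taken) + count}/{space}) too high for rejection sampling"
        )
    rows: list[np.ndarray] = []
    need = count
    while need:
        cand = rng.integers(0, 4, size=(need, l), dtype=np.uint8)
        keys = factors.pack(cand)
        for row, key in zip(cand, keys):
            k = int(key)
            if k not in taken:
                taken.add(k)
                rows.append(row)
        need = count - len(rows)
    return np.stack(rows)


def generate_random_set(
    l: int,
    n: int,
    seed: int | np.random.Generator | None = None,
    params: PenaltyParams = penalties.DEFAULT_PARAMS,
    min_overlap: int = 3,
) -> SetState:
    """Draw n distinct uniform random barcodes of length l and score them."""
    if l < 1:
        raise ValueError("barcode length must be >= 1")
    if n > 4**l:
        raise ValueError(f"cannot draw {n} distinct barcodes of length {l}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _draw_distinct(rng, l, n, set())
    return compute_state(codes, params, min_overlap)


def exclusion_probabilities(
    state: SetState,
    alpha: float,
    weights: Weights = penalties.DEFAULT_WEIGHTS,
    clip: bool = True,
) -> np.ndarray:
    """Per-barcode exclusion probabilities P_EX,i = P_Ti/P_WT * N * alpha.

    Pre-clip values sum exactly to N*alpha; with ``clip=True`` (the default)
    they are clipped into [0, 1] for use as Bernoulli probabilities.
    """
    p_ti = state.per_barcode_totals(weights)
    p_wt = p_ti.sum()
    if p_wt <= 0:
        raise ValueError("P_WT is zero: the set is already optimal, no exclusion round")
    p_ex = p_ti / p_wt * state.n * alpha
    return np.clip(p_ex, 0.0, 1.0) if clip else p_ex


def run_cycle(state: SetState, cfg: OptimizerConfig, rng: np.random.Generator) -> SetState:
    """One exclusion/replacement cycle; returns a new scored state of size N.

    Pairwise penalty columns are updated incrementally: survivors lose the
    pair scores they shared with removed barcodes and gain those against the
    replacements — equal (to rounding) to a full recompute.
    """
    if state.totals(cfg.weights).p_wt == 0:
        return state
    p_ex = exclusion_probabilities(state, cfg.alpha, cfg.weights)
    excluded = rng.random(state.n) < p_ex
    n_out = int(excluded.sum())
    if n_out == 0:
        return state
    keep = ~excluded
    kept_codes = state.codes[keep]
    taken = {int(k) for k in factors.pack(kept_codes)}
    new_codes = _draw_distinct(rng, cfg.l, n_out, taken)

    old_codes = state.codes[excluded]
    comp = np.vstack([state.components[keep], np.empty((n_out, 5))])
    codes = np.vstack([kept_codes, new_codes])

    new_slice = slice(len(kept_codes), None)
    comp[new_slice, 0] = penalties.p_gcc(factors.gc_content_array(new_codes), cfg.params)
    comp[new_slice, 1] = penalties.p_hp(factors.homopolymer_length_array(new_codes), cfg.params)
    comp[new_slice, 2] = penalties.p_sr(factors.ssr_repeats_array(new_codes), cfg.params)

    hd_rm, cp_rm = penalties.pair_scores_cross(kept_codes, old_codes, cfg.params, cfg.min_overlap)
    hd_ad, cp_ad = penalties.pair_scores_cross(kept_codes, new_codes, cfg.params, cfg.min_overlap)
    comp[: len(kept_codes), 3] += hd_ad.sum(axis=1) - hd_rm.sum(axis=1)
    comp[: len(kept_codes), 4] += cp_ad.sum(axis=1) - cp_rm.sum(axis=1)

    # new barcodes: pairs against survivors plus among themselves (minus self)
    hd_nn, cp_nn = penalties.pair_scores_cross(new_codes, codes, cfg.params, cfg.min_overlap)
    self_idx = np.arange(n_out)
    hd_nn[self_idx, len(kept_codes) + self_idx] = 0.0
    cp_nn[self_idx, len(kept_codes) + self_idx] = 0.0
    comp[new_slice, 3] = hd_nn.sum(axis=1)
    comp[new_slice, 4] = cp_nn.sum(axis=1)
    return SetState(codes, comp)


@dataclass
class Trace:
    """Per-cycle record of penalty totals of an optimization run."""

    records: list[dict] = field(default_factory=list)

    def append(self, cycle: int, totals: SetTotals) -> None:
        self.records.append({"cycle": cycle, **totals._asdict()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def p_wta(self) -> float:
        """Initial weighted total."""
        return self.records[0]["p_wt"]

    @property
    def p_wtb(self) -> float:
        """Lowest weighted total observed."""
        return min(r["p_wt"] for r in self.records)

    @property
    def best_cycle(self) -> int:
        best = min(self.records, key=lambda r: r["p_wt"])
        return best["cycle"]

    @property
    def p_dec(self) -> float:
        """Percent decrease of the objective from initial to best cycle."""
        return percent_decrease(self.p_wta, self.p_wtb)


def percent_decrease(p_a: float, p_b: float) -> float:
    """(p_a - p_b) / p_a * 100 — the standard performance measure."""
    if p_a <= 0:
        raise ValueError("percent decrease undefined for non-positive initial score")
    return (p_a - p_b) / p_a * 100.0


def optimize(
    cfg: OptimizerConfig,
    callback=None,
) -> tuple[SetState, Trace]:
    """Run the full two-step algorithm; returns (best state, trace).

    ``callback(cycle, state, totals)`` is invoked after the initial draw
    (cycle 0) and after every cycle, e.g. to write per-cycle output files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    state = generate_random_set(cfg.l, cfg.n, rng, cfg.params, cfg.min_overlap)
    trace = Trace()
    totals = state.totals(cfg.weights)
    trace.append(0, totals)
    if callback:
        callback(0, state, totals)
    best = state.copy()
    best_pwt = totals.p_wt
    stall = 0
    for cycle in range(1, cfg.max_cycles + 1):
        if best_pwt == 0:
            break
        state = run_cycle(state, cfg, rng)
        totals = state.totals(cfg.weights)
        trace.append(cycle, totals)
        if callback:
            callback(cycle, state, totals)
        if totals.p_wt < best_pwt:
            best = state.copy()
            best_pwt = totals.p_wt
            stall = 0
        else:
            stall += 1
        if stall >= cfg.patience:
            break
    return best, trace
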