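"""Penalty scores mapping barcode factors to costs, and set totals.

Each factor value is mapped to a non-negative penalty on a common 10^6-ish
scale, calibrated against the factor distributions of uniformly random
12-mers:

* ``P_GCC`` inverts a Gaussian fitted to the random GC-content distribution
  (amplitude 22662.54, mu = 50, sigma = 14.74996), normalized so the score
  is 0 for gcc in [40, 60] and 10^6 at gcc = 0 or 100.
* ``P_HP`` / ``P_SR`` invert exponentials fitted to the homopolymer and
  dinucleotide-repeat distributions (461428*e^(-1.31322*hp),
  15642980*e^(-3.010114*sr)); values <= 2 share the minimum penalty (2 for
  HP, 6 for SR) and the curves saturate near 10^6.
* ``P_HD`` encodes the probability that sequencing errors (per-base rate
  ~1/10^3) convert one barcode into another: 10^6, 10^3 and 1 for hd = 1, 2,
  3 and exactly 0 for hd >= 4.
* ``P_CP`` grows by a factor 10^2 per extra complementary base once the
  length-normalized complementarity cp~ = cp*12/l reaches 8, peaking at 10^8
  for a perfect reverse-complement pair; below the threshold it is 0.

The set objective is the weighted total P_WT = sum_k w_k * P_kt where the
P_kt are per-factor totals over the set; pairwise factors (HD, CP) attribute
each unordered pair's score to both members, so per-barcode totals P_Ti sum
exactly to P_WT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import factors

__all__ = [
    "PenaltyParams",
    "SetTotals",
    "Weights",
    "barcode_total_penalty",
    "component_matrix",
    "pair_component_sums",
    "pair_scores_cross",
    "gcc_bar",
    "p_cp",
    "p_gcc",
    "p_hd",
    "p_hp",
    "p_sr",
    "set_totals",
]

FACTOR_NAMES = ("gcc", "hp", "sr", "hd", "cp")


@dataclass(frozen=True)
class PenaltyParams:
    """Fitted constants and thresholds of the five penalty curves.

    Defaults are the published calibration for l = 12 random barcodes.
    """

    gcc_amp: float = 22662.54
    gcc_mu: float = 50.0
    gcc_sigma: float = 14.74996
    gcc_best_lo: float = 40.0
    gcc_best_hi: float = 60.0
    gcc_scale: float = 1e6

    hp_b: float = 461428.0
    hp_c: float = -1.31322
    hp_offset: float = 2.0

    sr_b: float = 15642980.0
    sr_c: float = -3.010114
    sr_offset: float = 6.0

    # rate is -ln(1000): each extra mismatch is another 1/10^3 error factor,
    # giving the exact 10^6 / 10^3 / 1 ladder at hd = 1, 2, 3
    hd_amp: float = 1e9
    hd_rate: float = -6.907755278982137  # -ln(1000)
    hd_shift: float = 7.524427e-16
    hd_zero_from: int = 4

    cp_amp: float = 9.999999e-17
    cp_rate: float = 4.60517
    cp_shift: float = 0.0009216598
    cp_ref_len: int = 12
    cp_threshold: float = 8.0

    def __post_init__(self) -> None:
        if min(self.gcc_amp, self.hp_b, self.sr_b, self.hd_amp, self.cp_amp) <= 0:
            raise ValueError("penalty curve amplitudes must be positive")
        if not self.gcc_best_lo < self.gcc_mu < self.gcc_best_hi:
            raise ValueError("gcc best range must bracket gcc_mu")


@dataclass(frozen=True)
class Weights:
    """Relative importance of the five factor penalties in the objective."""

    w1: float = 20.0  # GCC
    w2: float = 20.0  # HP
    w3: float = 20.0  # SR
    w4: float = 1.0   # HD
    w5: float = 1.0   # CP

    def __post_init__(self) -> None:
        arr = self.as_array()
        if (arr < 0).any():
            raise ValueError("weights must be non-negative")
        if not (arr > 0).any():
            raise ValueError("at least one weight must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5], dtype=float)


DEFAULT_PARAMS = PenaltyParams()
DEFAULT_WEIGHTS = Weights()


def _gauss(x: np.ndarray, p: PenaltyParams) -> np.ndarray:
    return p.gcc_amp * np.exp(-((x - p.gcc_mu) ** 2) / (2.0 * p.gcc_sigma**2))


def gcc_bar(gcc, params: PenaltyParams = DEFAULT_PARAMS):
    """Normalized GC score: gcc_scale on [best_lo, best_hi], otherwise the
    Gaussian normalized by its value at the band edge and scaled; its minimum
    over [0, 100] sits at gcc = 0 or 100."""
    g = np.asarray(gcc, dtype=float)
    if (g < 0).any() or (g > 100).any():
        raise ValueError("gcc must lie in [0, 100]")
    p = params
    norm = _gauss(np.asarray(p.gcc_best_lo), p)
    out = np.where(
        (g >= p.gcc_best_lo) & (g <= p.gcc_best_hi),
        p.gcc_scale,
        _gauss(g, p) / norm * p.gcc_scale,
    )
    return out if out.ndim else float(out)


def p_gcc(gcc, params: PenaltyParams = DEFAULT_PARAMS):
    """GC-content penalty: 0 on [best_lo, best_hi], gcc_scale at 0%/100%."""
    p = params
    gbar = np.asarray(gcc_bar(gcc, p))
    norm = _gauss(np.asarray(p.gcc_best_lo), p)
    gbar_min = float(_gauss(np.asarray(0.0), p) / norm * p.gcc_scale)
    score = (p.gcc_scale - gbar) / (p.gcc_scale - gbar_min) * p.gcc_scale
    return score if score.ndim else float(score)


def _p_exp_inverted(x, b_unused, c, offset, scale=1e6):
    # 10^6 - f(x)/f(2) * 10^6 + offset, with f(x) = b*e^(c*x); b cancels
    xbar = np.exp(c * (x - 2.0)) * scale
    return np.where(x <= 2, offset, scale - xbar + offset)


def p_hp(hp, params: PenaltyParams = DEFAULT_PARAMS):
    """Homopolymer penalty; hp <= 2 shares the minimum (hp_offset)."""
    h = np.asarray(hp, dtype=float)
    if (h < 1).any():
        raise ValueError("hp must be >= 1")
    score = _p_exp_inverted(h, params.hp_b, params.hp_c, params.hp_offset)
    return score if score.ndim else float(score)


def p_sr(sr, params: PenaltyParams = DEFAULT_PARAMS):
    """Dinucleotide-repeat penalty; sr <= 2 shares the minimum (sr_offset)."""
    s = np.asarray(sr, dtype=float)
    if (s < 1).any():
        raise ValueError("sr must be >= 1")
    score = _p_exp_inverted(s, params.sr_b, params.sr_c, params.sr_offset)
    return score if score.ndim else float(score)


def p_hd(hd, params: PenaltyParams = DEFAULT_PARAMS):
    """Hamming-distance penalty: ~10^6, 10^3, 1 at hd = 1, 2, 3; 0 from 4.

    hd = 0 (duplicate sequences) is scored at the full amplitude so that
    user-supplied sets containing duplicates are maximally penalized.
    """
    h = np.asarray(hd, dtype=float)
    if (h < 0).any():
        raise ValueError("hd must be >= 0")
    p = params
    score = np.where(
        h >= p.hd_zero_from,
        0.0,
        np.where(h == 0, p.hd_amp, p.hd_amp * np.exp(p.hd_rate * h) - p.hd_shift),
    )
    return score if score.ndim else float(score)


def p_cp(cp, l, params: PenaltyParams = DEFAULT_PARAMS):
    """Complementarity penalty on the length-normalized cp~ = cp*ref/l scale."""
    c = np.asarray(cp, dtype=float)
    if l <= 0:
        raise ValueError("barcode length must be positive")
    if (c < 0).any() or (c > l).any():
        raise ValueError("cp must lie in [0, l]")
    p = params
    ctil = c * p.cp_ref_len / l
    with np.errstate(over="ignore"):
        raw = p.cp_amp * np.exp(p.cp_rate * ctil) - p.cp_shift
    score = np.where(ctil < p.cp_threshold, 0.0, np.maximum(raw, 0.0))
    return score if score.ndim else float(score)


def _hd_score_lut(l: int, params: PenaltyParams) -> np.ndarray:
    return p_hd(np.arange(l + 1), params)


def _cp_score_lut(l: int, params: PenaltyParams) -> np.ndarray:
    return p_cp(np.arange(l + 1), l, params)


def barcode_total_penalty(components, weights: Weights = DEFAULT_WEIGHTS):
    """Weighted per-barcode total P_Ti from the five factor components."""
    comp = np.asarray(components, dtype=float)
    if (comp < 0).any():
        raise ValueError("penalty components must be non-negative")
    return comp @ weights.as_array()


class SetTotals(NamedTuple):
    """Per-factor totals of a barcode set and the weighted objective."""

    p_gcct: float
    p_hpt: float
    p_srt: float
    p_hdt: float
    p_cpt: float
    p_wt: float

    @classmethod
    def from_components(cls, components: np.ndarray, weights: Weights) -> "SetTotals":
        comp = np.asarray(components, dtype=float)
        totals = comp.sum(axis=0) if comp.size else np.zeros(5)
        p_wt = float(totals @ weights.as_array())
        return cls(*(float(t) for t in totals), p_wt)


def set_totals(components, weights: Weights = DEFAULT_WEIGHTS) -> SetTotals:
    """Factor totals and weighted objective from an (n, 5) component matrix."""
    return SetTotals.from_components(components, weights)


# ---------------------------------------------------------------------------
# set-level component computation
# ---------------------------------------------------------------------------

_CHUNK = 512


def pair_scores_cross(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    params: PenaltyParams = DEFAULT_PARAMS,
    min_overlap: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """(na, nb) matrices of pair HD and CP penalty scores."""
    codes_a = np.atleast_2d(codes_a)
    codes_b = np.atleast_2d(codes_b)
    l = codes_a.shape[1]
    pa, pb = factors.pack(codes_a), factors.pack(codes_b)
    rb = factors.pack(3 - codes_b[:, ::-1])
    hd_lut = _hd_score_lut(l, params)
    cp_lut = _cp_score_lut(l, params)
    hd_scores = hd_lut[factors.hamming_cross(pa, pb, l)]
    if l >= min_overlap:
        cp_scores = cp_lut[factors.complementarity_cross(pa, rb, l, min_overlap)]
    else:
        cp_scores = np.zeros_like(hd_scores)
    return hd_scores, cp_scores


def pair_component_sums(
    codes: np.ndarray,
    params: PenaltyParams = DEFAULT_PARAMS,
    min_overlap: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-barcode sums of pair HD and CP penalties over all N-1 partners.

    Each unordered pair contributes its score to both members, so the column
    sums are twice the sum over unordered pairs. Computed blockwise.
    """
    codes = np.atleast_2d(codes)
    n, l = codes.shape
    packed = factors.pack(codes)
    rc = factors.pack(3 - codes[:, ::-1])
    hd_lut = _hd_score_lut(l, params)
    cp_lut = _cp_score_lut(l, params)
    hd_comp = np.zeros(n)
    cp_comp = np.zeros(n)
    do_cp = l >= min_overlap
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        hd_blk = factors.hamming_cross(packed[start:stop], packed, l)
        scores = hd_lut[hd_blk]
        # remove the self term (hd = 0 scores as a duplicate penalty)
        idx = np.arange(start, stop)
        scores[idx - start, idx] = 0.0
        hd_comp[start:stop] = scores.sum(axis=1)
        if do_cp:
            cp_blk = factors.complementarity_cross(packed[start:stop], rc, l, min_overlap)
            cscores = cp_lut[cp_blk]
            cscores[idx - start, idx] = 0.0  # self-dimer excluded from set totals
            cp_comp[start:stop] = cscores.sum(axis=1)
    return hd_comp, cp_comp


def component_matrix(
    codes: np.ndarray,
    params: PenaltyParams = DEFAULT_PARAMS,
    min_overlap: int = 3,
) -> np.ndarray:
    """(n, 5) unweighted penalty components (GCC, HP, SR, HD, CP) of a set."""
    codes = np.atleast_2d(codes)
    comp = np.empty((codes.shape[0], 5))
    comp[:, 0] = p_gcc(factors.gc_content_array(codes), params)
    comp[:, 1] = p_hp(factors.homopolymer_length_array(codes), params)
    comp[:, 2] = p_sr(factors.ssr_repeats_array(codes), params)
    comp[:, 3], comp[:, 4] = pair_component_sums(codes, params, min_overlap)
    return comp
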