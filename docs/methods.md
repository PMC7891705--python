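# Methods

## Model

A barcode is an element of {A, C, G, T}^l; there are 4^l of them
(16 777 216 at l = 12). The package scores barcodes on five factors and
minimizes a weighted penalty total over a set of N distinct barcodes.

Per-barcode factors: GC content `gcc = 100·(n_G + n_C)/l`; homopolymer
length `hp`, the longest single-base run; simple-sequence-repeat count
`sr`, the largest number of tandem copies of any dinucleotide unit, with
both frame offsets scanned, runs allowed to start anywhere, and a
homopolymer run of length r counting as floor(r/2) copies of its XX unit
(trailing partial units do not count). Pairwise factors: Hamming distance
`hd` (ungapped mismatches, equal lengths only) and complementarity `cp`,
the maximum number of Watson–Crick pairings when one barcode (5'→3') is
slid along the other read 3'→5', over every offset with overlap ≥ 3 in
both directions. Pairings within the overlap need not be contiguous: the
factor measures total duplex-forming propensity, not the longest stem, and
the function is symmetric with cp(b, revcomp(b)) = l. Levenshtein distance
is computed (via edlib) for set-comparison reports only.

## Penalty curves

All curves are configuration (`PenaltyParams`); the defaults are the
calibration against uniform random 12-mers.

- **P_GCC** — Gaussian f(gcc) = 22662.54·exp(−(gcc−50)²/(2·14.74996²)),
  normalized as ḡcc = f(gcc)/f(40)·10⁶ with ḡcc fixed to 10⁶ on the best
  band [40, 60], then inverted:
  P_GCC = (10⁶ − ḡcc)/(10⁶ − min ḡcc)·10⁶. min ḡcc is evaluated from the
  formula at gcc = 0 (≈ 4023.17, rounding to the reference 4023) rather
  than hard-coded, so user-supplied curve constants stay consistent.
- **P_HP / P_SR** — exponentials f(hp) = 461428·e^(−1.31322·hp) and
  f(sr) = 15642980·e^(−3.010114·sr), normalized at the modal value 2 and
  inverted with offsets +2 and +6; values ≤ 2 share the minimum (2 and 6),
  since shorter motifs are unavoidable and harmless.
- **P_HD** — 10⁹·e^(−hd·ln 1000) − 7.524427·10⁻¹⁶ for hd = 1, 2, 3 and
  exactly 0 for hd ≥ 4: the probability that 1, 2 or 3 simultaneous
  sequencing errors (per-base rate 10⁻³) convert one barcode into another,
  rescaled by 10⁹. The decay rate is taken as −ln 1000 to full precision
  so the 10⁶/10³/1 ladder is exact; duplicate sequences (hd = 0), which
  the optimizer itself never produces, score the full 10⁹ amplitude so
  user-supplied duplicates are maximally penalized.
- **P_CP** — on the length-normalized scale c̃p = cp·12/l:
  9.999999·10⁻¹⁷·e^(4.60517·c̃p) − 0.0009216598 for c̃p ≥ 8, else 0,
  i.e. a hundredfold increase per extra complementary base from 1 at
  c̃p = 8 to 10⁸ at c̃p = 12 (perfect reverse complement). The threshold
  is held on the normalized scale (c̃p ≥ 8 ⇔ cp ≥ 2l/3), which reproduces
  both the c̃p = 8 anchor and the cp ≈ 5.33 cutoff at l = 8.

Weights default to (20, 20, 20, 1, 1) — the optimum of the published 4⁵
grid search, reproduced here at reduced scale by
`characterize.grid_search_weights`. The per-barcode total is
P_Ti = Σ w_k·P_k,i with pairwise components summed over the N−1 partners
(each unordered pair contributes to both members, so Σ_i P_Ti = P_WT
exactly); self-dimers are excluded from set totals.

## Optimizer

One seeded `numpy.random.Generator` drives, in order: the initial draw,
each cycle's Bernoulli exclusion draws, and replacement sampling — runs
are exactly reproducible. Exclusion probabilities P_Ti/P_WT·N·α are
clipped to [0, 1] (penalty-dominant barcodes exceed 1); exclusions are
independent Bernoulli draws, so α·N is the expected, not exact,
replacement count, and zero-penalty barcodes are never excluded.
Replacements are rejection-sampled to be distinct from survivors and from
each other; when a draw would be denser than half the space and the space
is enumerable (4^l ≤ 4^10), sampling switches to exact
without-replacement selection so small spaces (down to l = 1) can be
exhausted. Stopping: `patience` (default 5) consecutive cycles without
improving the running minimum, a hard `max_cycles` cap (default 200;
observed runs converge in ~10–40), or P_WT = 0. The arg-min state over
all cycles is returned, along with a per-cycle trace of all six totals
from which P_WTa, P_WTb and P_DEC = (P_WTa − P_WTb)/P_WTa·100 derive.

Sequences are held as 2-bit codes packed into uint64 words; pairwise hd
uses XOR + popcount and cp a per-shift XOR/mask scan (2(l−3)+1 shifts),
blockwise at 512 rows per chunk. Cycles update pairwise components
incrementally (survivors subtract removed-partner scores and add
replacement scores; O(αN²) per cycle instead of O(N²) pair kernels),
verified against full recomputation to 10⁻⁶ relative in the tests. Full
recomputation is used when scoring a set from scratch and when writing
output files. Desk-scale problems (N ≤ 5000) run in seconds; N = 10⁵ is
supported but takes hours single-threaded
(`scripts/reproduce_full_scale.py`).

## Synthetic data and what the tests show

All experimental inputs are uniform i.i.d. random barcodes — exactly the
population on which the penalty curves were calibrated and from which the
optimizer draws, so the generator is the study condition, not an
approximation of one. Test scales are reduced relative to the published
runs (N = 500–2000 vs 10⁵; single runs vs 1000 repetitions), chosen so the
suite completes in minutes: anchor values and distribution modes are
scale-free, but absolute P_WT magnitudes and the exact median P_DEC of the
full-scale setting are not checked at desk scale. Random-pair statistics
use uniform sampling of unordered pairs (with replacement) rather than all
N²/2 pairs; modes are insensitive to this. Mode ties break toward the
smaller value. hp/sr distribution summaries bucket values < 2 with 2
(penalties treat them identically). None of this models platform-specific
error profiles, synthesis bias, or real read data; passing tests show the
selection machinery behaves as designed on its own model population.

A deliberate departure from the expected desk-scale behavior is worth
recording: with default weights at N = 2000, optimization reliably purges
hd = 1 pairs and reduces P_HDt, but the raw count of pairs with hd ≤ 3
*increases*, because that count is dominated by hd = 3 pairs (penalty 1,
vs 10⁶ at hd = 1) while GC-balancing concentrates sequence composition
and slightly raises near-pair rates. The acceptance test asserting fewer
hd ≤ 3 pairs therefore fails by design of the measure, and the comparison
tests assert the directions that do hold (hd = 1 purged, GCC penalty and
hp ≥ 4 fraction reduced).

## Numerical and design choices

- Factor functions reject non-ACGT characters (including N/U) after
  uppercasing; no IUPAC ambiguity support. Thermodynamic duplex prediction
  is deliberately out of scope — cp counts base pairs.
- `hamming_lut` partitions a pair into sub-blocks of 4, then 3, then 2
  bases (l = 9 → 4+3+2, l = 10 → 4+4+2) and sums table look-ups; tables
  are dense arrays indexed by (code₁ << 2k) | code₂ and regenerate in
  milliseconds, so the hd2/hd3/hd4 table files are an optional cache.
- P_SR saturates to its 10⁶ + 6 float ceiling around sr ≈ 12; strict
  monotonicity holds over the realistic domain sr ≤ l/2.
- Curve refitting (`fit_penalty_curves`) follows the calibration recipe:
  Gaussian on mean counts per gcc value across sets, exponentials on
  median counts per hp/sr value restricted to values ≥ 2, constant terms
  dropped; scipy `curve_fit` with log-linear initialization.
- Parameter files use a `key = value` dialect with `#` comments; unknown
  and duplicate keys are errors. Resolution order: defaults < files < CLI
  flags. Output files sort barcodes with A < C < G < T (ASCII).
- Per-cycle output files use zero-padded cycle indices
  (`cycle_0000.txt` = initial state).

## Limitations

- Single-process; no multi-threading or GPU.
- Bit-packed kernels require l ≤ 31 (any practical barcode length).
- The optimizer is stochastic refinement, not exact: it guarantees a
  non-increasing best objective, not a global optimum, and exerts little
  pressure on factors whose penalties are small relative to P_WT (e.g.
  hd = 3 pairs under default weights).
- Levenshtein distance is reported for comparisons but not penalized
  during optimization.
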