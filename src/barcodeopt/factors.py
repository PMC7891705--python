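"""Barcode factor computations.

A barcode is a short oligonucleotide over {A, C, G, T} of fixed length ``l``;
there are ``4**l`` possible barcodes of a given length. Five factors describe
how well a barcode (or a pair of barcodes) behaves in a molecular-barcoding
(UMI) experiment:

``gcc``
    GC content, the percentage of G+C bases. Extreme GC content causes
    mispriming and amplification bias.
``hp``
    Homopolymer length, the longest run of a single base. Long homopolymers
    cause polymerase slippage and platform-specific indel errors.
``sr``
    Simple-sequence-repeat count, the largest number of tandem copies of any
    dinucleotide unit (a homopolymer run of length ``r`` counts as
    ``floor(r/2)`` copies of its ``XX`` unit). Another slippage-prone motif.
``hd``
    Hamming distance between two equal-length barcodes: mismatches in the
    ungapped alignment. Small distances make barcodes collapse into one
    another under sequencing errors (misclustering).
``cp``
    Complementarity: the maximum number of Watson-Crick base pairs formed by
    sliding one barcode along the other in antiparallel orientation with a
    minimum overlap (default 3). High values flag dimer-prone pairs.

Levenshtein distance (``ld``) is also provided for set-comparison reports.

Scalar functions operate on strings and are written as plain, auditable
loops. The ``*_array``/``*_cross`` variants operate on 2-bit integer code
arrays (A=0, C=1, G=2, T=3) and bit-packed 64-bit words for speed; both
routes are held to agree by the test suite.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable

import edlib
import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP_TABLE = str.maketrans("ACGT", "TGCA")

__all__ = [
    "BASES",
    "Barcode",
    "barcode_space_size",
    "HdLookupTables",
    "complement",
    "complementarity",
    "complementarity_cross",
    "decode",
    "encode",
    "gc_content",
    "gc_content_array",
    "hamming",
    "hamming_cross",
    "hamming_lut",
    "homopolymer_length",
    "homopolymer_length_array",
    "levenshtein",
    "pack",
    "reverse_complement",
    "ssr_repeats",
    "ssr_repeats_array",
    "validate_sequence",
]


def barcode_space_size(l: int) -> int:
    """Number of possible barcodes of length l over the 4-letter alphabet."""
    if l < 1:
        raise ValueError("barcode length must be >= 1")
    return 4**l


def validate_sequence(seq: str, min_length: int = 1) -> str:
    """Canonicalize a barcode sequence: uppercase, ACGT-only."""
    if not isinstance(seq, str):
        raise TypeError(f"barcode must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if len(s) < min_length:
        raise ValueError(f"barcode {seq!r} shorter than minimum length {min_length}")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(
            f"barcode {seq!r} contains characters outside ACGT: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class Barcode:
    """A validated fixed-length oligonucleotide over {A, C, G, T}."""

    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", validate_sequence(self.seq))

    @property
    def l(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq

    def __len__(self) -> int:
        return len(self.seq)


def _as_seq(b) -> str:
    return b.seq if isinstance(b, Barcode) else validate_sequence(b)


def complement(seq: str) -> str:
    return _as_seq(seq).translate(_COMP_TABLE)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def encode(seqs: Iterable[str] | str) -> np.ndarray:
    """Encode sequences as a (n, l) uint8 array with A=0, C=1, G=2, T=3."""
    if isinstance(seqs, (str, Barcode)):
        seqs = [seqs]
    rows = [_as_seq(s) for s in seqs]
    if not rows:
        return np.empty((0, 0), dtype=np.uint8)
    l = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != l:
            raise ValueError(f"sequence {i} has length {len(r)}, expected {l}")
    flat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.uint8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    return lut[flat].reshape(len(rows), l)


def decode(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.ndim == 1:
        codes = codes[None, :]
    chars = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return [bytes(chars[row]).decode("ascii") for row in codes]


def pack(codes: np.ndarray) -> np.ndarray:
    """Pack (n, l) 2-bit codes into uint64 words (l <= 31), base 0 in the
    highest-order field."""
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.ndim == 1:
        codes = codes[None, :]
    l = codes.shape[1]
    if l > 31:
        raise ValueError(f"cannot pack sequences longer than 31 bases (l={l})")
    packed = np.zeros(codes.shape[0], dtype=np.uint64)
    for j in range(l):
        packed = (packed << np.uint64(2)) | codes[:, j]
    return packed


def _lowbit_mask(l: int) -> np.uint64:
    """01 repeated in every 2-bit field: bit 0 of each of the l fields."""
    m = 0
    for _ in range(l):
        m = (m << 2) | 1
    return np.uint64(m)


# ---------------------------------------------------------------------------
# per-barcode factors
# ---------------------------------------------------------------------------

def gc_content(b) -> float:
    """GC content of a barcode as a percentage in [0, 100]."""
    s = _as_seq(b)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def homopolymer_length(b) -> int:
    """Length of the longest run of a single base (>= 1)."""
    s = _as_seq(b)
    best = run = 1
    for prev, cur in zip(s, s[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def ssr_repeats(b) -> int:
    """Largest number of tandem copies of any dinucleotide unit (>= 1).

    Both frame offsets are scanned and a run may start at any position;
    homopolymer runs count as copies of their XX unit, so "GGGGGG" is a
    3x"GG" repeat. Sequences shorter than one unit return 1.
    """
    s = _as_seq(b)
    l = len(s)
    if l < 2:
        return 1
    best = 1
    for p in range(l - 1):
        unit = s[p : p + 2]
        copies = 1
        q = p + 2
        while s[q : q + 2] == unit:
            copies += 1
            q += 2
        best = max(best, copies)
    return best


def gc_content_array(codes: np.ndarray) -> np.ndarray:
    codes = np.atleast_2d(np.asarray(codes, dtype=np.uint8))
    gc = (codes == _CODE["C"]) | (codes == _CODE["G"])
    return 100.0 * gc.sum(axis=1) / codes.shape[1]


def homopolymer_length_array(codes: np.ndarray) -> np.ndarray:
    codes = np.atleast_2d(np.asarray(codes, dtype=np.uint8))
    n, l = codes.shape
    best = np.ones(n, dtype=np.int64)
    run = np.ones(n, dtype=np.int64)
    for j in range(1, l):
        same = codes[:, j] == codes[:, j - 1]
        run = np.where(same, run + 1, 1)
        np.maximum(best, run, out=best)
    return best


def ssr_repeats_array(codes: np.ndarray) -> np.ndarray:
    codes = np.atleast_2d(np.asarray(codes, dtype=np.uint8))
    n, l = codes.shape
    if l < 4:
        return np.ones(n, dtype=np.int64)
    # chain[:, p] true when the unit at p equals the unit at p+2
    chain = (codes[:, : l - 3] == codes[:, 2 : l - 1]) & (
        codes[:, 1 : l - 2] == codes[:, 3:l]
    )
    copies = np.ones((n, l - 1), dtype=np.int64)
    for p in range(l - 4, -1, -1):
        copies[:, p] = np.where(chain[:, p], copies[:, p + 2] + 1, 1)
    return copies.max(axis=1)


# ---------------------------------------------------------------------------
# pairwise factors
# ---------------------------------------------------------------------------

def hamming(b1, b2) -> int:
    """Hamming distance between two equal-length barcodes."""
    s1, s2 = _as_seq(b1), _as_seq(b2)
    if len(s1) != len(s2):
        raise ValueError(
            f"hamming distance requires equal lengths, got {len(s1)} and {len(s2)}"
        )
    return sum(c1 != c2 for c1, c2 in zip(s1, s2))


def levenshtein(b1, b2) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    s1, s2 = _as_seq(b1), _as_seq(b2)
    return edlib.align(s1, s2, task="distance")["editDistance"]


def complementarity(b1, b2, min_overlap: int = 3) -> int:
    """Maximum Watson-Crick base pairs over all antiparallel ungapped offsets.

    One barcode (5'->3') is slid along the other read 3'->5'; at each offset
    with overlap >= ``min_overlap`` every aligned A-T or G-C pairing is
    counted (pairings need not be contiguous) and the maximum over offsets is
    returned. Symmetric in its arguments; ``cp(b, revcomp(b)) = l``.
    """
    s1, s2 = _as_seq(b1), _as_seq(b2)
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min(len(s1), len(s2)) < min_overlap:
        raise ValueError(
            f"sequences of lengths {len(s1)}, {len(s2)} cannot overlap by {min_overlap}"
        )
    # pairing b1[i] with b2[j] on the antiparallel diagonal i + j = k is the
    # same as matching b1 against reverse_complement(b2) at a parallel shift
    e = reverse_complement(s2)
    l1, l2 = len(s1), len(e)
    best = 0
    for shift in range(-(l1 - min_overlap), l2 - min_overlap + 1):
        count = 0
        for i in range(l1):
            j = i + shift
            if 0 <= j < l2 and s1[i] == e[j]:
                count += 1
        best = max(best, count)
    return best


def hamming_cross(packed_a: np.ndarray, packed_b: np.ndarray, l: int) -> np.ndarray:
    """(na, nb) Hamming-distance matrix from packed representations."""
    y = packed_a[:, None] ^ packed_b[None, :]
    mism = (y | (y >> np.uint64(1))) & _lowbit_mask(l)
    return np.bitwise_count(mism).astype(np.uint8)


def complementarity_cross(
    packed_a: np.ndarray,
    packed_rc_b: np.ndarray,
    l: int,
    min_overlap: int = 3,
) -> np.ndarray:
    """(na, nb) complementarity matrix.

    ``packed_rc_b`` must hold the packed *reverse complements* of the second
    set: cp(a, b) equals the best parallel-shift identity between a and
    revcomp(b).
    """
    if l < min_overlap:
        raise ValueError(f"l={l} below minimum overlap {min_overlap}")
    pa = packed_a[:, None]
    pb = packed_rc_b[None, :]
    mask01 = _lowbit_mask(l)
    best = np.zeros(np.broadcast_shapes(pa.shape, pb.shape), dtype=np.uint8)
    for s in range(0, l - min_overlap + 1):
        sh = np.uint64(2 * s)
        valid = np.uint64((int(mask01) >> (2 * s)) << (2 * s))
        for x, y in ((pa, pb), (pb, pa)) if s else ((pa, pb),):
            d = x ^ (y << sh)
            mism = (d | (d >> np.uint64(1))) & valid
            matches = (l - s) - np.bitwise_count(mism)
            np.maximum(best, matches.astype(np.uint8), out=best)
    return best


# ---------------------------------------------------------------------------
# Hamming look-up tables
# ---------------------------------------------------------------------------

def _block_plan(l: int) -> list[int]:
    """Partition l into blocks from {4, 3, 2}, greedily largest-first."""
    if l < 2:
        raise ValueError(f"length {l} cannot be tiled by blocks of 2-4 bases")
    q, r = divmod(l, 4)
    if r == 0:
        return [4] * q
    if r == 1:
        return [4] * (q - 1) + [3, 2]
    if r == 2:
        return [4] * q + [2]
    return [4] * q + [3]


@dataclass(frozen=True)
class HdLookupTables:
    """Dense precomputed Hamming distances for all ordered k-mer pairs,
    k = 2, 3, 4; table_k[(x << 2k) | y] = hd(x, y) for 2-bit-encoded k-mers."""

    tables: dict[int, np.ndarray] = field(repr=False)

    KS = (2, 3, 4)

    @classmethod
    def build(cls) -> "HdLookupTables":
        tables = {}
        for k in cls.KS:
            m = 4**k
            kmers = np.array(
                [[(i >> (2 * (k - 1 - j))) & 3 for j in range(k)] for i in range(m)],
                dtype=np.uint8,
            )
            hd = (kmers[:, None, :] != kmers[None, :, :]).sum(axis=2)
            tables[k] = hd.reshape(m * m).astype(np.uint8)
        return cls(tables=tables)

    def lookup(self, k: int, code1: int, code2: int) -> int:
        return int(self.tables[k][(code1 << (2 * k)) | code2])


@functools.lru_cache(maxsize=1)
def _default_luts() -> HdLookupTables:
    return HdLookupTables.build()


def _kmer_code(s: str) -> int:
    c = 0
    for ch in s:
        c = (c << 2) | _CODE[ch]
    return c


def hamming_lut(b1, b2, luts: HdLookupTables | None = None) -> int:
    """Hamming distance via precomputed sub-block tables.

    The pair is partitioned into sub-blocks of 4, then 3, then 2 bases
    (l=8 -> 4+4, l=9 -> 4+3+2, l=10 -> 4+4+2) and block distances are summed
    from the look-up tables. Identical to :func:`hamming` for every l >= 2.
    """
    s1, s2 = _as_seq(b1), _as_seq(b2)
    if len(s1) != len(s2):
        raise ValueError("hamming_lut requires equal lengths")
    luts = luts or _default_luts()
    total = 0
    pos = 0
    for k in _block_plan(len(s1)):
        total += luts.lookup(k, _kmer_code(s1[pos : pos + k]), _kmer_code(s2[pos : pos + k]))
        pos += k
    return total
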