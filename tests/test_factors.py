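"""Factor computations: worked examples, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodeopt import factors as f

from oracles import cp_bruteforce, hamming_naive, levenshtein_dp

dna = st.text(alphabet="ACGT", min_size=1, max_size=16)
dna4 = st.text(alphabet="ACGT", min_size=4, max_size=16)


class TestScalarFactors:
    @pytest.mark.parametrize(
        "seq, expected",
        [("AGCTAAGCTACC", 50.0), ("AAAA", 0.0), ("GGCC", 100.0), ("ACGT", 50.0)],
    )
    def test_gc_content(self, seq, expected):
        assert f.gc_content(seq) == expected

    @pytest.mark.parametrize(
        "seq, expected",
        [("GTAAACGGGGGC", 5), ("ACGT", 1), ("AATTCCC", 3), ("A", 1)],
    )
    def test_homopolymer_length(self, seq, expected):
        assert f.homopolymer_length(seq) == expected

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GGGGGG", 3),        # a homopolymer run is a tandem XX repeat
            ("ACGT", 1),
            ("TATCTCTCTCGA", 4),  # TCTCTCTC = 4 x TC
            ("A", 1),
            ("AGAGAG", 3),
            ("TCTCT", 2),         # trailing partial unit does not count
        ],
    )
    def test_ssr_repeats(self, seq, expected):
        assert f.ssr_repeats(seq) == expected

    @pytest.mark.parametrize(
        "s1, s2, expected",
        [("AAAAC", "AGAAG", 2), ("ACGT", "ACGT", 0), ("ACGTACGTA", "TGCATGCAT", None)],
    )
    def test_hamming(self, s1, s2, expected):
        expected = hamming_naive(s1, s2) if expected is None else expected
        assert f.hamming(s1, s2) == expected

    def test_hamming_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            f.hamming("ACGT", "ACG")

    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("AGACAT", "GTGTCC", 4),  # GACA reverse-complements TGTC
            ("AAAA", "TTTT", 4),
        ],
    )
    def test_complementarity_examples(self, s1, s2, expected):
        assert f.complementarity(s1, s2) == expected

    def test_complementarity_full_duplex(self):
        b = "ACGTTGCAGGTA"
        assert f.complementarity(b, f.reverse_complement(b)) == len(b)

    def test_complementarity_overlap_infeasible(self):
        with pytest.raises(ValueError, match="overlap"):
            f.complementarity("AC", "ACGT", min_overlap=3)

    @pytest.mark.parametrize(
        "s1, s2, expected",
        [("AAAAC", "AGAAG", 2), ("ACGT", "ACGT", 0), ("ACGT", "CGT", 1)],
    )
    def test_levenshtein(self, s1, s2, expected):
        assert f.levenshtein(s1, s2) == expected

    @pytest.mark.parametrize("bad", ["ACGN", "ACGU", "AC-T", ""])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            f.validate_sequence(bad)

    def test_lowercase_canonicalized(self):
        assert f.gc_content("acgt") == 50.0


class TestLookupTables:
    def test_table_sizes_and_identity(self):
        luts = f.HdLookupTables.build()
        for k in (2, 3, 4):
            assert luts.tables[k].size == 4**k * 4**k
            for code in range(4**k):
                assert luts.lookup(k, code, code) == 0
            assert luts.tables[k].max() == k

    def test_block_plan_matches_stated_decompositions(self):
        assert f._block_plan(8) == [4, 4]
        assert f._block_plan(9) == [4, 3, 2]
        assert f._block_plan(10) == [4, 4, 2]
        assert f._block_plan(2) == [2]
        with pytest.raises(ValueError):
            f._block_plan(1)

    def test_hamming_lut_exhaustive_l4(self):
        codes = np.array(
            [[(i >> (2 * (3 - j))) & 3 for j in range(4)] for i in range(256)],
            dtype=np.uint8,
        )
        seqs = f.decode(codes)
        packed = f.pack(codes)
        hd = f.hamming_cross(packed, packed, 4)
        for i in range(0, 256, 17):
            for j in range(256):
                assert f.hamming_lut(seqs[i], seqs[j]) == hd[i, j]

    @pytest.mark.parametrize("l", [8, 9, 10, 12])
    def test_hamming_lut_equals_hamming(self, l, random_seqs):
        a = random_seqs(300, l, seed=l)
        b = random_seqs(300, l, seed=l + 100)
        for s1, s2 in zip(a, b):
            assert f.hamming_lut(s1, s2) == f.hamming(s1, s2)


class TestVectorizedAgreement:
    @pytest.mark.parametrize("l", [4, 7, 12])
    def test_per_barcode_arrays_match_scalars(self, l, random_seqs):
        seqs = random_seqs(200, l)
        codes = f.encode(seqs)
        np.testing.assert_allclose(
            f.gc_content_array(codes), [f.gc_content(s) for s in seqs]
        )
        np.testing.assert_array_equal(
            f.homopolymer_length_array(codes), [f.homopolymer_length(s) for s in seqs]
        )
        np.testing.assert_array_equal(
            f.ssr_repeats_array(codes), [f.ssr_repeats(s) for s in seqs]
        )

    @pytest.mark.parametrize("l", [6, 8, 12])
    def test_cross_kernels_match_scalars(self, l, random_seqs):
        seqs = random_seqs(25, l)
        codes = f.encode(seqs)
        packed = f.pack(codes)
        rc = f.pack(3 - codes[:, ::-1])
        hd = f.hamming_cross(packed, packed, l)
        cp = f.complementarity_cross(packed, rc, l)
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                assert hd[i, j] == f.hamming(seqs[i], seqs[j])
                assert cp[i, j] == f.complementarity(seqs[i], seqs[j])

    def test_encode_decode_roundtrip(self, random_seqs):
        seqs = random_seqs(50, 12)
        assert f.decode(f.encode(seqs)) == seqs


class TestOracles:
    @pytest.mark.parametrize("l", [6, 8, 12])
    def test_complementarity_against_bruteforce(self, l, random_seqs):
        a = random_seqs(60, l, seed=7 * l)
        b = random_seqs(60, l, seed=7 * l + 1)
        for s1, s2 in zip(a, b):
            assert f.complementarity(s1, s2) == cp_bruteforce(s1, s2)

    def test_levenshtein_against_dp(self, random_seqs):
        a = random_seqs(50, 9, seed=1)
        b = random_seqs(50, 12, seed=2)
        for s1, s2 in zip(a, b):
            assert f.levenshtein(s1, s2) == levenshtein_dp(s1, s2)

    @pytest.mark.parametrize("l", [5, 10])
    def test_levenshtein_bounded_by_hamming(self, l, random_seqs):
        a = random_seqs(100, l, seed=3)
        b = random_seqs(100, l, seed=4)
        for s1, s2 in zip(a, b):
            assert f.levenshtein(s1, s2) <= f.hamming(s1, s2)


class TestProperties:
    @given(dna)
    def test_gc_content_reversal_invariant(self, s):
        assert f.gc_content(s[::-1]) == f.gc_content(s)

    @given(dna)
    def test_gc_content_of_complement(self, s):
        assert f.gc_content(f.complement(s)) == pytest.approx(f.gc_content(s))

    @given(dna)
    def test_hp_sr_reversal_invariant(self, s):
        assert f.homopolymer_length(s[::-1]) == f.homopolymer_length(s)
        assert f.ssr_repeats(s[::-1]) == f.ssr_repeats(s)

    @given(dna)
    def test_sr_at_least_half_hp(self, s):
        # a homopolymer run of length r contains floor(r/2) XX-unit copies
        assert f.ssr_repeats(s) >= f.homopolymer_length(s) // 2

    @given(dna4, dna4)
    def test_complementarity_symmetric(self, s1, s2):
        assert f.complementarity(s1, s2) == f.complementarity(s2, s1)

    @given(dna4)
    def test_complementarity_of_revcomp_is_length(self, s):
        assert f.complementarity(s, f.reverse_complement(s)) == len(s)

    @given(dna4, dna4)
    def test_hamming_symmetric_and_bounded(self, s1, s2):
        s2 = s2[: len(s1)].ljust(len(s1), "A")
        hd = f.hamming(s1, s2)
        assert hd == f.hamming(s2, s1)
        assert 0 <= hd <= len(s1)
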