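"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately takes a different computational route than the
package: complementarity enumerates antiparallel diagonals directly on the
two strings (no reverse-complement trick), Levenshtein is the classic
dynamic program, and the pairwise set totals are a plain double loop over
scalar functions.
"""

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def cp_bruteforce(s1: str, s2: str, min_overlap: int = 3) -> int:
    """Max Watson-Crick pairings of b1[i] with b2[j] over diagonals i+j=k."""
    l1, l2 = len(s1), len(s2)
    best = 0
    for k in range(l1 + l2 - 1):
        pairs = 0
        overlap = 0
        for i in range(l1):
            j = k - i
            if 0 <= j < l2:
                overlap += 1
                if _WC[s1[i]] == s2[j]:
                    pairs += 1
        if overlap >= min_overlap:
            best = max(best, pairs)
    return best


def levenshtein_dp(s1: str, s2: str) -> int:
    prev = list(range(len(s2) + 1))
    for i, c1 in enumerate(s1, 1):
        cur = [i]
        for j, c2 in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (c1 != c2)))
        prev = cur
    return prev[-1]


def hamming_naive(s1: str, s2: str) -> int:
    assert len(s1) == len(s2)
    return sum(a != b for a, b in zip(s1, s2))
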