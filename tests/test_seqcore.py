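"""Degenerate-alphabet primitives and the stem-loop finder."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reptag import seqcore
from reptag.catalog import load_target_palindromes
from reptag.seqcore import (
    InvalidSequenceError,
    PalindromeHit,
    bases_pair,
    check_gapped_palindrome,
    find_palindromes,
    match_consensus,
    matches_code,
    reverse_complement,
)

ALPHA = "ACGTRYKMSWBDHVN"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "T"), ("T", "G")}


def brute_force_palindromes(seq, min_arm, max_arm, min_loop, max_loop,
                            max_mismatch, allow_wobble):
    """Exhaustive enumeration over all (start, arm, loop) triples.

    Maximality applied afterwards: for each loop interval only the
    longest qualifying arm survives. Kept deliberately independent of
    the production scanner.
    """
    n = len(seq)
    best = {}
    for start in range(n):
        for arm in range(min_arm, max_arm + 1):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * arm + loop
                if end > n:
                    continue
                mism = wob = 0
                for i in range(arm):
                    pair = (seq[start + i], seq[end - 1 - i])
                    if pair in _WC:
                        continue
                    if allow_wobble and pair in _WOB:
                        wob += 1
                    else:
                        mism += 1
                if mism > max_mismatch:
                    continue
                key = (start + arm, loop)  # the loop interval
                if key not in best or arm > best[key][1]:
                    best[key] = (start, arm, loop, mism, wob)
    return sorted(best.values(), key=lambda h: (h[0], -h[1], h[2]))


def as_tuples(hits):
    return [(h.start, h.arm_len, h.loop_len, h.mismatches, h.wobble_pairs)
            for h in hits]


class TestMatchesCode:
    @pytest.mark.parametrize(
        "base,code,expected",
        [("A", "R", True), ("G", "R", True), ("C", "R", False),
         ("C", "Y", True), ("T", "Y", True), ("G", "N", True),
         ("T", "K", True), ("A", "M", True), ("G", "S", True),
         ("A", "W", True), ("C", "B", True), ("A", "B", False),
         ("A", "H", True), ("G", "H", False), ("G", "V", True),
         ("T", "V", False), ("A", "D", True), ("C", "D", False),
         ("A", "A", True), ("A", "C", False)],
    )
    def test_code_sets(self, base, code, expected):
        assert matches_code(base, code) is expected

    def test_rejects_non_alphabet(self):
        with pytest.raises(InvalidSequenceError):
            matches_code("X", "R")
        with pytest.raises(InvalidSequenceError):
            matches_code("A", "Z")
        with pytest.raises(InvalidSequenceError):
            matches_code("R", "N")  # first argument must be concrete


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTAG", "CTAC"),
            ("CCGSSCC", "GGSSCGG"),
            # the printed 27 bp target-palindrome arm and its partner arm
            ("TTTCANNAATCAAATNNNANTCCTATA",
             "TATAGGANTNNNATTTGATTNNTGAAA"),
        ],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet=ALPHA, min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_invalid(self):
        with pytest.raises(InvalidSequenceError):
            reverse_complement("ACGU")


class TestBasesPair:
    @pytest.mark.parametrize(
        "a,b,wobble,expected",
        [("G", "C", False, True), ("C", "G", False, True),
         ("A", "T", False, True), ("T", "A", False, True),
         ("G", "T", True, True), ("T", "G", True, True),
         ("G", "T", False, False), ("A", "C", True, False),
         ("A", "A", True, False), ("C", "T", True, False)],
    )
    def test_pairing_table(self, a, b, wobble, expected):
        assert bases_pair(a, b, allow_wobble=wobble) is expected

    def test_rejects_degenerate(self):
        with pytest.raises(InvalidSequenceError):
            bases_pair("R", "Y")


class TestMatchConsensus:
    @pytest.mark.parametrize(
        "window,consensus,expected",
        [("GGCCCGG", "GGSSCGG", 0), ("GGTCCGG", "GGSSCGG", 1),
         ("ACGT", "ACGT", 0), ("ACGT", "NNNN", 0), ("AAAA", "CCCC", 4)],
    )
    def test_counts(self, window, consensus, expected):
        assert match_consensus(window, consensus) == expected

    def test_length_mismatch(self):
        with pytest.raises(InvalidSequenceError):
            match_consensus("ACG", "ACGT")


class TestFindPalindromes:
    def test_small_target_palindrome(self):
        # a 7 bp arm / 3 bp loop instance of the CCGSSCC (n3,4) GGSSCGG
        # small-palindrome consensus, S resolved to G/C
        hits = find_palindromes("CCGGGCCAAAGGCCCGG", min_arm=7, max_arm=7,
                                min_loop=3, max_loop=4, max_mismatch=0)
        assert as_tuples(hits) == [(0, 7, 3, 0, 0)]

    def test_unpairable_sequence(self):
        assert find_palindromes("A" * 16, min_arm=5, max_arm=8,
                                min_loop=0, max_loop=4) == []

    def test_empty_sequence(self):
        assert find_palindromes("", 2, 5) == []

    def test_wobble_counted_separately(self):
        # GT arm pairs only via wobble: arms GTT / AGC -> G:C, T:G, T:A
        hits = find_palindromes("GTTAAAGC", min_arm=3, max_arm=3,
                                min_loop=2, max_loop=2, max_mismatch=0,
                                allow_wobble=True)
        assert len(hits) == 1
        assert hits[0].wobble_pairs == 1
        assert hits[0].mismatches == 0
        assert find_palindromes("GTTAAAGC", 3, 3, 2, 2, 0,
                                allow_wobble=False) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence(self, seed):
        import random

        r = random.Random(seed)
        n = r.choice([60, 150, 400])
        seq = "".join(r.choice("ACGT") for _ in range(n))
        kwargs = dict(min_arm=4, max_arm=7, min_loop=0, max_loop=6,
                      max_mismatch=r.choice([0, 1]),
                      allow_wobble=bool(seed % 2))
        assert as_tuples(find_palindromes(seq, **kwargs)) == \
            brute_force_palindromes(seq, **kwargs)

    @pytest.mark.parametrize("seed", range(6))
    def test_mirror_symmetry(self, seed):
        # G:T wobble is not complement-closed (the mirrored pair is A:C),
        # so the coordinate-mirror invariant holds for strict pairing
        import random

        r = random.Random(seed + 100)
        seq = "".join(r.choice("ACGT") for _ in range(200))
        fwd = find_palindromes(seq, 4, 6, 0, 5, 0, allow_wobble=False)
        rev = find_palindromes(reverse_complement(seq), 4, 6, 0, 5, 0,
                               allow_wobble=False)
        mirrored = sorted(
            (len(seq) - h.span - h.start, h.arm_len, h.loop_len,
             h.mismatches, h.wobble_pairs)
            for h in rev
        )
        assert mirrored == sorted(as_tuples(fwd))

    @pytest.mark.parametrize("seed", range(6))
    def test_mismatch_monotonicity(self, seed):
        import random

        r = random.Random(seed + 200)
        seq = "".join(r.choice("ACGT") for _ in range(200))
        loose = {(h.start + h.arm_len, h.loop_len)
                 for h in find_palindromes(seq, 4, 6, 0, 5, 2)}
        tight = {(h.start + h.arm_len, h.loop_len)
                 for h in find_palindromes(seq, 4, 6, 0, 5, 0)}
        # raising the budget never loses a loop interval
        assert tight <= loose


class TestGappedPalindromeConsensus:
    def test_dimer_target_consensi(self):
        targets = load_target_palindromes()
        n, ok, ncap = check_gapped_palindrome(
            targets["H_neapolitanus_CGTC-1"]
        )
        assert (n, ok) == (41, True)
        n, ok, ncap = check_gapped_palindrome(
            targets["A_variabilis_GTAG-15"]
        )
        assert (n, ok) == (54, True)

    def test_broken_pairing_detected(self):
        assert check_gapped_palindrome("GGGG••AAAA")[1] is False
        assert check_gapped_palindrome("GGGG••CCCC")[1] is True
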