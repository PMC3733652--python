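"""Degenerate-alphabet sequence primitives.

Everything downstream of the scanner is built on four small operations:
membership of a concrete base in an NC-IUB degeneracy code, degenerate
reverse complementation, Watson-Crick pairing with optional G:T wobble
(REP stems are frequently stabilised by G:T pairs, a hallmark of elements
that act at the RNA level), and consensus matching with mismatch counts.
On top of these sits a stem-loop (palindrome) finder that enumerates
candidate (start, arm, loop) geometries directly; it is deliberately
simple enough to be verifiable against exhaustive enumeration.

Coordinates are 0-based half-open throughout this package; GFF3 emission
converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

#: NC-IUB degeneracy codes -> set of concrete bases they denote.
#: The full IUPAC set is supported, including D (A,G,T), which is required
#: to complement H even though printed consensi rarely use it.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

ALPHABET = frozenset(IUPAC_SETS)
CONCRETE = frozenset("ACGT")

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


class InvalidSequenceError(ValueError):
    """A character fell outside the expected nucleotide alphabet."""


def _validate(seq: str, allowed: frozenset[str], what: str) -> str:
    up = seq.upper()
    bad = set(up) - allowed
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-alphabet character(s): {sorted(bad)!r}"
        )
    return up


def matches_code(base: str, code: str) -> bool:
    """True iff concrete ``base`` is in the set denoted by IUPAC ``code``.

    ``N`` matches every base; a concrete code matches only itself.
    """
    b = base.upper()
    c = code.upper()
    if b not in CONCRETE:
        raise InvalidSequenceError(f"expected a concrete base, got {base!r}")
    if c not in ALPHABET:
        raise InvalidSequenceError(f"unknown degeneracy code {code!r}")
    return b in IUPAC_SETS[c]


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full degenerate alphabet.

    Degenerate codes complement setwise (R<->Y, K<->M, S<->S, W<->W,
    B<->V, H<->D, N<->N), so the operation is an involution.
    """
    up = _validate(seq, ALPHABET, "sequence")
    return str(_bio_revcomp(up))


def bases_pair(a: str, b: str, allow_wobble: bool = True) -> bool:
    """Watson-Crick pairing of two concrete bases, optionally with G:T wobble.

    Pairing is defined on concrete bases only; degenerate codes are rejected.
    """
    pa, pb = a.upper(), b.upper()
    for x in (pa, pb):
        if x not in CONCRETE:
            raise InvalidSequenceError(
                f"pairing is defined on concrete bases, got {x!r}"
            )
    pair = (pa, pb)
    if pair in _WC_PAIRS:
        return True
    return allow_wobble and pair in _WOBBLE_PAIRS


def match_consensus(window: str, consensus: str) -> int:
    """Number of positions of ``window`` violating the degenerate ``consensus``.

    Returns 0 for an exact degenerate match. Lengths must agree.
    """
    w = _validate(window, CONCRETE, "window")
    c = _validate(consensus, ALPHABET, "consensus")
    if len(w) != len(c):
        raise InvalidSequenceError(
            f"window length {len(w)} != consensus length {len(c)}"
        )
    return sum(1 for x, y in zip(w, c) if x not in IUPAC_SETS[y])


@dataclass(frozen=True, order=True)
class PalindromeHit:
    """One stem-loop: ``arm_len`` paired bases around a ``loop_len`` loop.

    ``mismatches`` counts arm position pairs failing ``bases_pair``;
    ``wobble_pairs`` counts G:T pairings used (never counted as mismatches).
    """

    start: int
    arm_len: int
    loop_len: int
    mismatches: int = 0
    wobble_pairs: int = 0

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.loop_len

    @property
    def end(self) -> int:
        return self.start + self.span


def _arm_stats(seq: str, start: int, arm: int, loop: int,
               allow_wobble: bool) -> tuple[int, int]:
    """(mismatches, wobble_pairs) for the stem of a candidate geometry."""
    mism = 0
    wob = 0
    right_last = start + 2 * arm + loop - 1
    for i in range(arm):
        a = seq[start + i]
        b = seq[right_last - i]
        if bases_pair(a, b, allow_wobble=False):
            continue
        if allow_wobble and (a, b) in _WOBBLE_PAIRS:
            wob += 1
        else:
            mism += 1
    return mism, wob


def find_palindromes(
    seq: str,
    min_arm: int,
    max_arm: int,
    min_loop: int = 0,
    max_loop: int = 10,
    max_mismatch: int = 0,
    allow_wobble: bool = True,
) -> list[PalindromeHit]:
    """All maximal stem-loops in ``seq`` within the given geometry bounds.

    For every loop interval, only the longest qualifying arm (at most
    ``max_arm``) is reported: a hit wholly contained in a longer-armed hit
    around the same loop is suppressed. Hits are sorted by start, then
    longer arm, then shorter loop.
    """
    if min_arm < 1:
        raise ValueError("min_arm must be >= 1")
    if max_arm < min_arm or max_loop < min_loop or min_loop < 0:
        raise ValueError("inconsistent geometry bounds")
    s = _validate(seq, ALPHABET, "sequence") if seq else ""
    n = len(s)
    hits: list[PalindromeHit] = []
    # Iterate loop placements; extend the arm outward to the longest length
    # with total mismatches <= max_mismatch.
    for loop in range(min_loop, max_loop + 1):
        for loop_start in range(0, n - loop + 1):
            best: PalindromeHit | None = None
            limit = min(max_arm, loop_start, n - loop_start - loop)
            if limit < min_arm:
                continue
            mism = 0
            wob = 0
            for arm in range(1, limit + 1):
                a = s[loop_start - arm]
                b = s[loop_start + loop + arm - 1]
                if a in CONCRETE and b in CONCRETE and bases_pair(
                    a, b, allow_wobble=False
                ):
                    pass
                elif (
                    allow_wobble
                    and a in CONCRETE
                    and b in CONCRETE
                    and (a, b) in _WOBBLE_PAIRS
                ):
                    wob += 1
                else:
                    mism += 1
                if arm >= min_arm and mism <= max_mismatch:
                    best = PalindromeHit(
                        start=loop_start - arm,
                        arm_len=arm,
                        loop_len=loop,
                        mismatches=mism,
                        wobble_pairs=wob,
                    )
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: (h.start, -h.arm_len, h.loop_len))
    return hits


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence}."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


# ---------------------------------------------------------------------------
# Gapped-palindrome consensus checks (printed target palindromes)
# ---------------------------------------------------------------------------

def check_gapped_palindrome(
    consensus: str, allow_wobble: bool = True
) -> tuple[int, bool, int]:
    """Validate a printed target-palindrome consensus string.

    Such consensi are printed as ``LEFT••RIGHT`` where dots mark the
    insertion point of the repeat dimer, capital letters denote bases that
    pair between the two halves, lowercase letters unpaired/variable bases,
    and ``-`` an alignment gap. The two halves are aligned outside-in
    (left half 5'->3' against right half 3'->5'), with gaps honoured.

    Returns ``(n_residues, capitals_all_pair, n_capital_columns)`` where
    ``n_residues`` counts nucleotide characters only (separators stripped).
    """
    mid = None
    for sep in ("••", "..", "**"):
        if sep in consensus:
            mid = consensus.index(sep)
            left = consensus[:mid]
            right = consensus[mid + len(sep):]
            break
    if mid is None:
        half = len(consensus) // 2
        left, right = consensus[:half], consensus[half:]
    residues = [c for c in left + right if c not in "-"]
    n_residues = len(residues)
    lchars = list(left)
    rchars = list(reversed(right))
    n_cols = max(len(lchars), len(rchars))
    lchars += ["-"] * (n_cols - len(lchars))
    rchars += ["-"] * (n_cols - len(rchars))
    ok = True
    n_capital = 0
    for a, b in zip(lchars, rchars):
        if a.isupper() and b.isupper():
            n_capital += 1
            if a.upper() == "N" or b.upper() == "N":
                continue
            if not bases_pair(a, b, allow_wobble=allow_wobble):
                ok = False
        elif a.isupper() or b.isupper():
            # a capital facing a gap or lowercase cannot pair
            ok = False
    return n_residues, ok, n_capital
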