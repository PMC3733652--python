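"""Genome scanning for tagged stem-loop elements.

The scan is a deterministic consensus search: for every catalog family,
every occurrence of a permitted tag 4-mer (canonical or listed degenerate
variant) seeds candidate geometries (arm variant x loop length), which are
accepted when the arm consensus holds up to a mismatch budget. Both
strands are scanned; overlapping candidates are resolved to the best
explanation (fewest mismatches, then longer stem, then leftmost, then
catalog order). Pruning is a separate pass, mirroring the two-phase
procedure the method follows: elements with more than one mismatch in the
paired region are discarded unless partnered in a dimer, and elements
whose loops are unusual for length or composition relative to their
family are discarded outright.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from . import seqcore
from .catalog import FamilyDefinition
from .seqcore import IUPAC_SETS, bases_pair, reverse_complement

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: scan-time mismatch ceiling; two-mismatch elements stay discoverable as
#: dimer partners and are removed later by :func:`prune_elements`.
DEFAULT_MAX_STEM_MISMATCH = 2
#: post-pairing ceiling for elements that are not dimer partners.
DEFAULT_PRUNE_MISMATCH = 1


@dataclass(frozen=True)
class RepElement:
    """One detected tagged stem-loop element (0-based half-open coords)."""

    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    tag_seq: str
    extra_seq: str
    arm5_seq: str
    loop_seq: str
    arm3_seq: str
    tail_seq: str
    stem_mismatches: int
    consensus_mismatches: int
    wobble_pairs: int
    loop_class: str | None = None
    loop_ok: bool = True
    catalog_index: int = field(default=0, compare=False)
    tag_end: str = field(default="five_prime", compare=False)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def sequence_type(self) -> str:
        """ST key: the left (5') stem arm sequence on the element strand."""
        return self.arm5_seq

    @property
    def tag_at_start(self) -> bool:
        """True when the tag occupies the genomic-left end of the element."""
        return (self.strand == "+") == (self.tag_end == "five_prime")


def degenerate_to_regex(consensus: str) -> str:
    return "".join(
        "[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in consensus.upper()
    )


def _mismatches_capped(window: str, consensus: str, cap: int) -> int:
    """Mismatch count vs a degenerate consensus, aborting beyond ``cap``."""
    mism = 0
    for b, c in zip(window, consensus):
        if b not in IUPAC_SETS[c]:
            mism += 1
            if mism > cap:
                return mism
    return mism


def _stem_stats(arm5: str, arm3: str, allow_wobble: bool) -> tuple[int, int]:
    mism = 0
    wob = 0
    n = len(arm5)
    for i in range(n):
        a, b = arm5[i], arm3[n - 1 - i]
        if bases_pair(a, b, allow_wobble=False):
            continue
        if allow_wobble and bases_pair(a, b, allow_wobble=True):
            wob += 1
        else:
            mism += 1
    return mism, wob


def _loop_assessment(
    defn: FamilyDefinition, loop: str
) -> tuple[str | None, bool]:
    """(loop class label, composition-plausible?) for a candidate loop."""
    if defn.loop_classes:
        for left, right in defn.loop_classes:
            if len(loop) >= len(left) + len(right):
                if (
                    _mismatches_capped(loop[: len(left)], left, 0) == 0
                    and _mismatches_capped(loop[-len(right):], right, 0) == 0
                ):
                    return f"{left}/{right}", True
        return None, False
    if defn.loop_consensus is not None and len(loop) == len(
        defn.loop_consensus
    ):
        return None, _mismatches_capped(loop, defn.loop_consensus, 0) == 0
    if defn.loop_consensus is not None:
        return None, False
    return None, True


def _scan_variants(defn: FamilyDefinition):
    yield defn
    for name in defn.species_variants:
        yield defn.variant(name)


@dataclass(frozen=True)
class _Candidate:
    start: int
    end: int
    strand: str
    family_id: str
    catalog_index: int
    tag_end: str
    segments: tuple[str, str, str, str, str, str]
    arm_mism: int
    stem_mism: int
    wobble: int
    loop_class: str | None
    loop_ok: bool


def _candidates_on_strand(
    seq: str,
    strand: str,
    defn: FamilyDefinition,
    catalog_index: int,
    max_stem_mismatch: int,
    allow_wobble: bool,
) -> list[_Candidate]:
    n = len(seq)
    out: dict[int, _Candidate] = {}
    tag_len = 4
    pattern = re.compile(
        "(?=(" + "|".join(degenerate_to_regex(t) for t in defn.all_tags) + "))"
    )
    extra = defn.extra_bases or ""
    tail = defn.tail or ""
    for variant in _scan_variants(defn):
        arms = [(a, reverse_complement(a)) for a in variant.arms]
        lo, hi = variant.loop_range
        for m in pattern.finditer(seq):
            p = m.start()
            best = out.get(p)
            for arm_cons, arm_rc in arms:
                arm_len = len(arm_cons)
                a5 = p + tag_len + len(extra)
                for loop_len in range(lo, hi + 1):
                    end = a5 + 2 * arm_len + loop_len + len(tail)
                    if end > n:
                        continue
                    if extra and _mismatches_capped(
                        seq[p + tag_len: a5], extra, 0
                    ):
                        continue
                    arm5 = seq[a5: a5 + arm_len]
                    m5 = _mismatches_capped(arm5, arm_cons, max_stem_mismatch)
                    if m5 > max_stem_mismatch:
                        continue
                    a3 = a5 + arm_len + loop_len
                    arm3 = seq[a3: a3 + arm_len]
                    m3 = _mismatches_capped(
                        arm3, arm_rc, max_stem_mismatch - m5
                    )
                    if m5 + m3 > max_stem_mismatch:
                        continue
                    if tail and _mismatches_capped(
                        seq[a3 + arm_len: end], tail, 0
                    ):
                        continue
                    stem_mism, wob = _stem_stats(arm5, arm3, allow_wobble)
                    if stem_mism > max_stem_mismatch:
                        continue
                    loop = seq[a5 + arm_len: a3]
                    loop_class, loop_ok = _loop_assessment(variant, loop)
                    cand = _Candidate(
                        start=p,
                        end=end,
                        strand=strand,
                        family_id=defn.family_id,
                        catalog_index=catalog_index,
                        tag_end=defn.tag_end,
                        segments=(
                            seq[p: p + tag_len],
                            seq[p + tag_len: a5],
                            arm5,
                            loop,
                            arm3,
                            seq[a3 + arm_len: end],
                        ),
                        arm_mism=m5 + m3,
                        stem_mism=stem_mism,
                        wobble=wob,
                        loop_class=loop_class,
                        loop_ok=loop_ok,
                    )
                    if best is None or (
                        (cand.arm_mism, not cand.loop_ok, -(end - p))
                        < (best.arm_mism, not best.loop_ok,
                           -(best.end - best.start))
                    ):
                        best = cand
            if best is not None:
                out[p] = best
    return list(out.values())


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter


def scan_tagged_elements(
    genome: dict[str, str],
    catalog: list[FamilyDefinition],
    max_stem_mismatch: int = DEFAULT_MAX_STEM_MISMATCH,
    allow_wobble: bool = True,
) -> list[RepElement]:
    """Scan all contigs on both strands for catalog-tagged elements.

    Candidates overlapping by at least half of the shorter one are
    competing explanations of the same locus; the winner has the fewest
    arm-consensus mismatches, then the longer stem, then the leftmost
    start, then the earlier catalog family.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    min_span = min(
        4 + 2 * min((len(a) for a in d.arms), default=5) + d.loop_range[0]
        for d in catalog
    )
    elements: list[RepElement] = []
    counter = 0
    for contig in sorted(genome):
        seq = genome[contig].upper()
        n = len(seq)
        if n < min_span:
            logger.info(
                "contig %s shorter than minimal element (%d bp): skipped",
                contig, min_span,
            )
            continue
        cands: list[_Candidate] = []
        rc = reverse_complement(seq)
        for idx, defn in enumerate(catalog):
            if defn.partial:
                continue
            for strand, s in (("+", seq), ("-", rc)):
                for c in _candidates_on_strand(
                    s, strand, defn, idx, max_stem_mismatch, allow_wobble
                ):
                    if strand == "-":
                        start = n - c.end
                        end = n - c.start
                        c = _Candidate(
                            start=start, end=end, strand="-",
                            family_id=c.family_id,
                            catalog_index=c.catalog_index,
                            tag_end=c.tag_end,
                            segments=c.segments,
                            arm_mism=c.arm_mism, stem_mism=c.stem_mism,
                            wobble=c.wobble, loop_class=c.loop_class,
                            loop_ok=c.loop_ok,
                        )
                    cands.append(c)
        # Overlap resolution order. The final keys are the candidate's own
        # segment sequences (identical however the genome is oriented), so
        # competing explanations of one locus resolve the same way on a
        # reverse-complemented genome; coordinates are a last resort only.
        cands.sort(
            key=lambda c: (
                c.arm_mism,
                not c.loop_ok,
                -(c.end - c.start),
                c.catalog_index,
                c.segments,
                c.start,
                c.strand,
            )
        )
        accepted: list[_Candidate] = []
        for c in cands:
            if any(
                _overlap_frac((c.start, c.end), (a.start, a.end)) >= 0.5
                for a in accepted
            ):
                continue
            accepted.append(c)
        accepted.sort(key=lambda c: (c.start, c.end, c.strand))
        for c in accepted:
            counter += 1
            tag, extra, arm5, loop, arm3, tail = c.segments
            elements.append(
                RepElement(
                    element_id=f"rep{counter:05d}",
                    contig=contig,
                    start=c.start,
                    end=c.end,
                    strand=c.strand,
                    family_id=c.family_id,
                    tag_seq=tag,
                    extra_seq=extra,
                    arm5_seq=arm5,
                    loop_seq=loop,
                    arm3_seq=arm3,
                    tail_seq=tail,
                    stem_mismatches=c.stem_mism,
                    consensus_mismatches=c.arm_mism,
                    wobble_pairs=c.wobble,
                    loop_class=c.loop_class,
                    loop_ok=c.loop_ok,
                    catalog_index=c.catalog_index,
                    tag_end=c.tag_end,
                )
            )
    return elements


def assign_family(
    segments: dict[str, str],
    catalog: list[FamilyDefinition],
    max_stem_mismatch: int = DEFAULT_MAX_STEM_MISMATCH,
) -> tuple[str, dict[str, int]] | tuple[None, None]:
    """Best family for a pre-segmented candidate, or (None, None).

    ``segments`` holds the element-strand sequences keyed tag/extra/arm5/
    loop/arm3/tail (missing keys default to empty). The best family has
    the fewest total consensus mismatches; ties go to catalog order; a
    listed tag variant counts as a variant, not a mismatch. Candidates
    whose best arm mismatch total exceeds the ceiling are unassignable.
    """
    tag = segments.get("tag", "")
    arm5 = segments.get("arm5", "")
    loop = segments.get("loop", "")
    arm3 = segments.get("arm3", "")
    extra = segments.get("extra", "")
    tail = segments.get("tail", "")
    best: tuple[int, int, str, dict[str, int]] | None = None
    for idx, defn in enumerate(catalog):
        for variant in _scan_variants(defn):
            if variant.partial or not variant.tag_matches(tag):
                continue
            for arm_cons in variant.arms:
                if len(arm_cons) != len(arm5) or len(arm5) != len(arm3):
                    continue
                lo, hi = variant.loop_range
                if not lo <= len(loop) <= hi:
                    continue
                if len(extra) != len(variant.extra_bases or ""):
                    continue
                if len(tail) != len(variant.tail or ""):
                    continue
                vec = {
                    "extra": (
                        seqcore.match_consensus(extra, variant.extra_bases)
                        if extra else 0
                    ),
                    "arm5": seqcore.match_consensus(arm5, arm_cons),
                    "arm3": seqcore.match_consensus(
                        arm3, reverse_complement(arm_cons)
                    ),
                    "tail": (
                        seqcore.match_consensus(tail, variant.tail)
                        if tail else 0
                    ),
                }
                total = sum(vec.values())
                key = (total, idx, defn.family_id, vec)
                if best is None or key[:2] < best[:2]:
                    best = key
    if best is None:
        return None, None
    total, idx, family_id, vec = best
    if vec["arm5"] + vec["arm3"] > max_stem_mismatch:
        return None, None
    return family_id, vec


def prune_elements(
    elements: list[RepElement],
    partner_map: dict[str, str],
    catalog: list[FamilyDefinition],
    max_mismatch: int = DEFAULT_PRUNE_MISMATCH,
) -> list[RepElement]:
    """Discard weakly paired singletons and loop outliers.

    An element survives when its loop is typical for its family (length
    inside the family range, composition fitting the family loop
    consensus or a loop class) and either its stem has at most
    ``max_mismatch`` unpaired positions or it is partnered in a dimer.
    Idempotent; output is a subset of input.
    """
    by_id = {d.family_id: d for d in catalog}
    kept = []
    for el in elements:
        defn = by_id.get(el.family_id)
        if defn is not None:
            ranges = [defn.loop_range] + [
                defn.variant(v).loop_range for v in defn.species_variants
            ]
            if not any(lo <= len(el.loop_seq) <= hi for lo, hi in ranges):
                continue
            if not el.loop_ok:
                continue
        if el.stem_mismatches <= max_mismatch or el.element_id in partner_map:
            kept.append(el)
    return kept


def sequence_type_census(elements: list[RepElement]) -> pd.DataFrame:
    """Counts of elements per (family, sequence type).

    STs are keyed on the left-arm sequence; counts partition the
    family-assigned elements.
    """
    rows = [
        {"family_id": el.family_id, "sequence_type": el.sequence_type}
        for el in elements
        if el.family_id != UNASSIGNED
    ]
    if not rows:
        return pd.DataFrame(columns=["family_id", "sequence_type", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["family_id", "sequence_type"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out


def elements_to_frame(elements: list[RepElement]) -> pd.DataFrame:
    """Element table in the shape of the TSV output."""
    return pd.DataFrame(
        [
            {
                "element_id": el.element_id,
                "contig": el.contig,
                "start": el.start,
                "end": el.end,
                "strand": el.strand,
                "family_id": el.family_id,
                "sequence_type": el.sequence_type,
                "tag_seq": el.tag_seq,
                "extra_seq": el.extra_seq,
                "arm5_seq": el.arm5_seq,
                "loop_seq": el.loop_seq,
                "arm3_seq": el.arm3_seq,
                "tail_seq": el.tail_seq,
                "stem_mismatches": el.stem_mismatches,
                "consensus_mismatches": el.consensus_mismatches,
                "wobble_pairs": el.wobble_pairs,
                "loop_class": el.loop_class or "",
            }
            for el in elements
        ]
    )


def write_elements_gff3(elements: list[RepElement], path) -> None:
    """Emit elements as GFF3 ``repeat_region`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            attrs = (
                f"ID={el.element_id};family={el.family_id};"
                f"sequence_type={el.sequence_type};"
                f"stem_mismatches={el.stem_mismatches}"
            )
            fh.write(
                "\t".join(
                    [
                        el.contig,
                        "reptag",
                        "repeat_region",
                        str(el.start + 1),
                        str(el.end),
                        ".",
                        el.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
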