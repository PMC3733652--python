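"""Chromosomal arrangement of elements: singletons, dimers, clusters.

Nearby repeats associate into dimers whose type follows the relative
orientation of the two partners: tag motifs pointing outward give
head-head (HH) dimers, inward tail-tail (TT), tandem arrangements
head-tail (HT) — heads being the stem-loop bodies and tails the terminal
tag motifs. Dimers are homodimers (identical partners), heterodimers
(same family, different stem and/or loop) or hybrids (different
families). Runs of three or more elements within the gap threshold are
grouped elements (clusters), the smallest being trimers (a singleton
next to a dimer). The spacer between dimer partners is characterised by
its length, complementary ends and any embedded stem-loops, features
that let a dimer fold into one large secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqcore import PalindromeHit, bases_pair, find_palindromes


@dataclass(frozen=True)
class DimerRecord:
    dimer_id: str
    members: tuple[str, str]
    contig: str
    topo: str  # HH | TT | HT
    spacer_start: int
    spacer_end: int
    composition: str | None = None  # homodimer | heterodimer | hybrid
    adjacent: bool = False  # partners within 5 bp

    @property
    def spacer_len(self) -> int:
        return self.spacer_end - self.spacer_start


@dataclass(frozen=True)
class ClusterRecord:
    cluster_id: str
    members: tuple[str, ...]
    contig: str
    sub_dimers: tuple[str, ...] = ()
    composition: str = ""


@dataclass(frozen=True)
class SpacerFeatures:
    length: int
    complementary_end_len: int
    embedded_sls: tuple[PalindromeHit, ...] = ()


@dataclass
class TopologyPartition:
    """Mutually exclusive, exhaustive S/D/G partition of the elements."""

    singletons: list = field(default_factory=list)
    dimers: list[DimerRecord] = field(default_factory=list)
    clusters: list[ClusterRecord] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)

    def conservation_identity(self) -> tuple[int, int]:
        """(S + 2·D + Σ|G|, elements covered) — both sides of the identity."""
        lhs = (
            len(self.singletons)
            + 2 * len(self.dimers)
            + sum(len(c.members) for c in self.clusters)
        )
        return lhs, len(self.roles)


def _dimer_topo(left, right) -> str:
    """Dimer type from the tag placement of the two partners.

    The tag sits at the element's 5' end on the element strand (catalog
    families may override), so a plus-strand element carries its tag at
    the genomic-left end. Tags outward -> HH, inward -> TT, tandem -> HT.
    """
    if left.tag_at_start and not right.tag_at_start:
        return "HH"
    if not left.tag_at_start and right.tag_at_start:
        return "TT"
    return "HT"


def pair_dimers(
    elements: Sequence, max_spacer: int = 100
) -> tuple[list[DimerRecord], dict[str, str]]:
    """Greedy left-to-right pairing of adjacent elements per contig.

    Each element joins at most one dimer; partners must lie on the same
    contig with an inner gap between 0 and ``max_spacer`` bp. Runs of
    three or more are re-examined by :func:`group_clusters`, which
    supersedes pairing inside clusters.
    """
    dimers: list[DimerRecord] = []
    partner: dict[str, str] = {}
    ordered = sorted(elements, key=lambda e: (e.contig, e.start, e.end))
    i = 0
    while i < len(ordered) - 1:
        a, b = ordered[i], ordered[i + 1]
        gap = b.start - a.end
        if a.contig == b.contig and 0 <= gap <= max_spacer:
            dimers.append(
                DimerRecord(
                    dimer_id=f"dimer{len(dimers) + 1:04d}",
                    members=(a.element_id, b.element_id),
                    contig=a.contig,
                    topo=_dimer_topo(a, b),
                    spacer_start=a.end,
                    spacer_end=b.start,
                    adjacent=gap <= 5,
                )
            )
            partner[a.element_id] = b.element_id
            partner[b.element_id] = a.element_id
            i += 2
        else:
            i += 1
    return dimers, partner


def classify_composition(dimer: DimerRecord, elements_by_id: dict) -> str | None:
    """homodimer / heterodimer / hybrid, or None when a member is unassigned.

    Hybrid dimers join members of different families; for the family
    census their components are counted as singletons of their own
    families rather than as a dimer of either.
    """
    a = elements_by_id[dimer.members[0]]
    b = elements_by_id[dimer.members[1]]
    from .detect import UNASSIGNED

    fam_a = getattr(a, "family_id", None)
    fam_b = getattr(b, "family_id", None)
    if fam_a is None or fam_b is None:
        return None  # family-less occurrences (e.g. TIR copies)
    if UNASSIGNED in (fam_a, fam_b):
        return None
    if a.family_id != b.family_id:
        return "hybrid"
    same_body = (
        a.arm5_seq == b.arm5_seq
        and a.loop_seq == b.loop_seq
        and a.arm3_seq == b.arm3_seq
    )
    return "homodimer" if same_body else "heterodimer"


def classify_dimers(dimers: list[DimerRecord], elements: Sequence
                    ) -> list[DimerRecord]:
    by_id = {e.element_id: e for e in elements}
    return [
        DimerRecord(
            dimer_id=d.dimer_id, members=d.members, contig=d.contig,
            topo=d.topo, spacer_start=d.spacer_start,
            spacer_end=d.spacer_end,
            composition=classify_composition(d, by_id),
            adjacent=d.adjacent,
        )
        for d in dimers
    ]


def group_clusters(
    elements: Sequence,
    dimers: list[DimerRecord],
    gap: int = 100,
) -> tuple[list[ClusterRecord], list[DimerRecord]]:
    """Maximal runs of >=3 elements within ``gap`` become clusters.

    Dimers whose members fall inside a cluster are recorded as the
    cluster's sub-structure and removed from the standalone dimer list.
    """
    ordered = sorted(elements, key=lambda e: (e.contig, e.start, e.end))
    runs: list[list] = []
    run: list = []
    for el in ordered:
        if run and el.contig == run[-1].contig and (
            el.start - run[-1].end
        ) <= gap and el.start >= run[-1].end:
            run.append(el)
        else:
            if len(run) >= 3:
                runs.append(run)
            run = [el]
    if len(run) >= 3:
        runs.append(run)

    clusters: list[ClusterRecord] = []
    absorbed: set[str] = set()
    for k, members in enumerate(runs, start=1):
        ids = {e.element_id for e in members}
        subs = [d for d in dimers if set(d.members) <= ids]
        absorbed.update(d.dimer_id for d in subs)
        n_sub = len(subs)
        n_single = len(members) - 2 * n_sub
        parts = []
        if n_single:
            parts.append(f"{n_single}S")
        parts += [f"D({d.topo})" for d in subs]
        clusters.append(
            ClusterRecord(
                cluster_id=f"cluster{k:04d}",
                members=tuple(e.element_id for e in members),
                contig=members[0].contig,
                sub_dimers=tuple(d.dimer_id for d in subs),
                composition="+".join(parts),
            )
        )
    kept = [d for d in dimers if d.dimer_id not in absorbed]
    return clusters, kept


def partition_elements(
    elements: Sequence, max_spacer: int = 100, cluster_gap: int = 100
) -> TopologyPartition:
    """Full S/D/G partition: every element gets exactly one role."""
    dimers, _ = pair_dimers(elements, max_spacer=max_spacer)
    dimers = classify_dimers(dimers, elements)
    clusters, dimers = group_clusters(elements, dimers, gap=cluster_gap)
    roles: dict[str, str] = {}
    clustered = {eid for c in clusters for eid in c.members}
    paired = {eid for d in dimers for eid in d.members}
    singletons = []
    for el in elements:
        if el.element_id in clustered:
            roles[el.element_id] = "G"
        elif el.element_id in paired:
            roles[el.element_id] = "D"
        else:
            roles[el.element_id] = "S"
            singletons.append(el)
    return TopologyPartition(
        singletons=singletons, dimers=dimers, clusters=clusters, roles=roles
    )


def complementary_end_len(spacer: str) -> int:
    """Longest k with the spacer prefix pairing the reverse of its suffix.

    Pairing is strict Watson-Crick (wobble off) and runs outside-in until
    the first failure; bounded by half the spacer length.
    """
    n = len(spacer)
    k = 0
    while k < n // 2 and bases_pair(
        spacer[k], spacer[n - 1 - k], allow_wobble=False
    ):
        k += 1
    return k


def analyze_spacer(
    dimer: DimerRecord,
    contig_seq: str,
    min_arm: int = 4,
    max_loop: int = 8,
) -> SpacerFeatures:
    """Structural features of a dimer spacer.

    Embedded stem-loops are called with perfect arms (no mismatches, no
    wobble) of at least ``min_arm`` bp around loops up to ``max_loop`` bp.
    """
    spacer = contig_seq[dimer.spacer_start: dimer.spacer_end].upper()
    if not spacer:
        return SpacerFeatures(length=0, complementary_end_len=0)
    sls = find_palindromes(
        spacer,
        min_arm=min_arm,
        max_arm=max(min_arm, len(spacer) // 2),
        min_loop=0,
        max_loop=max_loop,
        max_mismatch=0,
        allow_wobble=False,
    )
    return SpacerFeatures(
        length=len(spacer),
        complementary_end_len=complementary_end_len(spacer),
        embedded_sls=tuple(sls),
    )
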