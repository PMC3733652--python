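"""Relation of elements to the coding landscape.

Intergenic elements are classified by the orientation of the nearest
flanking ORFs — between convergently (conv), divergently (div) or
unidirectionally (uni) transcribed genes — with distances measured to
the facing ORF boundary. Elements wholly inside a coding sequence of at
least 120 codons are intragenic (shorter hypothetical ORFs are treated
as annotation noise and excluded); their in-frame encoded peptide and
position along the ORF (NH2 / internal / COOH) are reported. Elements
whose tag supplies the TAG stop codon of an adjacent ORF are flagged.

Tyrosine-transposase genes are classified by their flanking repeats:
REP monomers/dimers within a window make a REPtron, long terminal
inverted repeats (TIRs) with no REP evidence a TIRtron. TIR arms share a
motif fitting the consensus GGGGWSAS; once a TIR arm is known its
genome-wide family can be censused with the same singleton/dimer/group
partition used for REPs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .detect import RepElement, degenerate_to_regex
from .seqcore import reverse_complement
from .topology import partition_elements

#: conserved motif shared by TIR arms near tyrosine-transposase genes
TIR_MOTIF = "GGGGWSAS"

DEFAULT_MIN_AA = 120


@dataclass(frozen=True)
class OrfRecord:
    orf_id: str
    contig: str
    start: int
    end: int
    strand: str
    product_len_aa: int
    annotation: str = ""

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContextRecord:
    element_id: str
    category: str  # conv | div | uni | intragenic | contig_edge
    upstream_orf: str | None = None
    downstream_orf: str | None = None
    dist_upstream: int | None = None
    dist_downstream: int | None = None
    upstream_boundary: str | None = None  # 3' or 5' end of the upstream ORF
    downstream_boundary: str | None = None
    region: str | None = None  # NH2 | internal | COOH (intragenic only)
    encoded_peptide: str | None = None
    provides_stop: bool = False
    flagged: bool = False


@dataclass(frozen=True)
class TirArmPair:
    up_start: int
    up_end: int
    down_start: int
    down_end: int
    arm_len: int
    mismatches: int
    up_seq: str
    down_seq: str
    five_ov: bool = False
    three_ov: bool = False


@dataclass(frozen=True)
class TirtronCall:
    gene_id: str
    kind: str  # REPtron | TIRtron | none
    rep_ids: tuple[str, ...] = ()
    tir_pairs: tuple[TirArmPair, ...] = ()
    dist_upstream: int | None = None
    dist_downstream: int | None = None
    tir_note: bool = False  # REPtron with TIR-like flanks also present


# ---------------------------------------------------------------------------
# Annotation input
# ---------------------------------------------------------------------------

def read_orfs_gff3(path: str | Path) -> list[OrfRecord]:
    """CDS features from a GFF3 file (via gffutils, in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    orfs = []
    for i, feat in enumerate(db.features_of_type("CDS"), start=1):
        start = feat.start - 1  # to 0-based half-open
        end = feat.end
        if "product_length" in feat.attributes:
            aa = int(feat.attributes["product_length"][0])
        else:
            aa = (end - start) // 3 - 1
        orfs.append(
            OrfRecord(
                orf_id=feat.attributes.get("ID", [f"cds{i}"])[0],
                contig=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                product_len_aa=aa,
                annotation=feat.attributes.get("product", [""])[0],
            )
        )
    return sorted(orfs, key=lambda o: (o.contig, o.start, o.end))


def read_orfs_genbank(path: str | Path) -> list[OrfRecord]:
    """CDS features from a GenBank flat file."""
    from Bio import SeqIO

    orfs = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(rec.features, start=1):
            if feat.type != "CDS":
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "+" if feat.location.strand >= 0 else "-"
            quals = feat.qualifiers
            orf_id = quals.get("locus_tag", quals.get("protein_id",
                                                      [f"{rec.id}_cds{i}"]))[0]
            orfs.append(
                OrfRecord(
                    orf_id=orf_id,
                    contig=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product_len_aa=(end - start) // 3 - 1,
                    annotation=quals.get("product", [""])[0],
                )
            )
    return sorted(orfs, key=lambda o: (o.contig, o.start, o.end))


# ---------------------------------------------------------------------------
# Intergenic context
# ---------------------------------------------------------------------------

def _facing_boundary(orf: OrfRecord, side: str) -> str:
    """Which ORF end (3' or 5') faces an element on the given side."""
    if side == "left":  # element right of the ORF; facing end is orf.end
        return "3'" if orf.strand == "+" else "5'"
    return "5'" if orf.strand == "+" else "3'"


def classify_context(element: RepElement, orfs: list[OrfRecord]
                     ) -> ContextRecord:
    """Intergenic category of one element from its nearest flanking ORFs.

    Flanks are the nearest ORFs on each side that do not contain the
    element (partial overlap is tolerated — elements often abut or
    slightly overlap the 3' end of a gene whose stop codon they supply —
    and yields distance 0). A missing flank makes the element
    contig_edge.
    """
    same = [o for o in orfs if o.contig == element.contig]
    left = None
    for o in same:
        if o.start < element.start and o.end < element.end:
            if left is None or o.end > left.end:
                left = o
    right = None
    for o in same:
        if o.end > element.end and o.start > element.start:
            if right is None or o.start < right.start:
                right = o
    if left is None or right is None:
        return ContextRecord(
            element_id=element.element_id,
            category="contig_edge",
            upstream_orf=left.orf_id if left else None,
            downstream_orf=right.orf_id if right else None,
            dist_upstream=(max(0, element.start - left.end)
                           if left else None),
            dist_downstream=(max(0, right.start - element.end)
                             if right else None),
        )
    if left.strand == "+" and right.strand == "-":
        category = "conv"
    elif left.strand == "-" and right.strand == "+":
        category = "div"
    else:
        category = "uni"
    return ContextRecord(
        element_id=element.element_id,
        category=category,
        upstream_orf=left.orf_id,
        downstream_orf=right.orf_id,
        dist_upstream=max(0, element.start - left.end),
        dist_downstream=max(0, right.start - element.end),
        upstream_boundary=_facing_boundary(left, "left"),
        downstream_boundary=_facing_boundary(right, "right"),
    )


def find_intragenic(
    elements: list[RepElement],
    orfs: list[OrfRecord],
    genome: dict[str, str],
    min_aa: int = DEFAULT_MIN_AA,
    edge_fraction: float = 0.10,
) -> list[ContextRecord]:
    """Elements lying wholly within coding sequences of >= ``min_aa`` codons.

    The region label follows the element's codon span: NH2 when it starts
    within the first ``edge_fraction`` of codons, COOH when it ends within
    the last, internal otherwise. The encoded peptide translates the
    complete in-frame codons overlapping the element, in ORF orientation
    (bacterial code, table 11); partial codons at the element edges are
    excluded.
    """
    out = []
    for el in elements:
        host = None
        for o in orfs:
            if (
                o.contig == el.contig
                and o.start <= el.start
                and o.end >= el.end
                and o.product_len_aa >= min_aa
            ):
                if host is None or o.length_nt < host.length_nt:
                    host = o
        if host is None:
            continue
        flagged = host.length_nt % 3 != 0
        peptide = None
        region = None
        if not flagged:
            cds = genome[el.contig][host.start: host.end]
            if host.strand == "-":
                cds = reverse_complement(cds)
                off_start = host.end - el.end
                off_end = host.end - el.start
            else:
                off_start = el.start - host.start
                off_end = el.end - host.start
            first = math.ceil(off_start / 3)
            last = off_end // 3
            if last > first:
                peptide = str(
                    Seq(cds[first * 3: last * 3]).translate(table=11)
                )
            else:
                peptide = ""
            n_codons = host.length_nt // 3 - 1  # exclude stop
            lo = edge_fraction * n_codons
            hi = (1 - edge_fraction) * n_codons
            first_codon = off_start / 3
            last_codon = off_end / 3
            if first_codon <= lo:
                region = "NH2"
            elif last_codon >= hi:
                region = "COOH"
            else:
                region = "internal"
        out.append(
            ContextRecord(
                element_id=el.element_id,
                category="intragenic",
                upstream_orf=host.orf_id,
                downstream_orf=host.orf_id,
                dist_upstream=el.start - host.start,
                dist_downstream=host.end - el.end,
                region=region,
                encoded_peptide=peptide,
                flagged=flagged,
            )
        )
    return out


def classify_all_contexts(
    elements: list[RepElement],
    orfs: list[OrfRecord],
    genome: dict[str, str],
    min_aa: int = DEFAULT_MIN_AA,
) -> list[ContextRecord]:
    """One category per element; intragenic takes precedence."""
    intra = {
        r.element_id: r
        for r in find_intragenic(elements, orfs, genome, min_aa=min_aa)
    }
    records = []
    for el in elements:
        if el.element_id in intra:
            records.append(intra[el.element_id])
        else:
            rec = classify_context(el, orfs)
            stop = False
            if rec.upstream_orf is not None and rec.dist_upstream == 0:
                up = next(o for o in orfs if o.orf_id == rec.upstream_orf)
                stop = provides_stop(el, up, genome)
            if not stop and rec.downstream_orf is not None \
                    and rec.dist_downstream == 0:
                down = next(
                    o for o in orfs if o.orf_id == rec.downstream_orf
                )
                stop = provides_stop(el, down, genome)
            if stop:
                rec = ContextRecord(
                    **{**rec.__dict__, "provides_stop": True}
                )
            records.append(rec)
    return records


def provides_stop(element: RepElement, orf: OrfRecord,
                  genome: dict[str, str]) -> bool:
    """Does the element's tag supply the ORF's TAG stop codon?

    True iff the TAG trinucleotide inside the element's tag motif
    coincides, in genome coordinates and orientation, with the ORF's own
    TAG stop codon. The element must be within 3 bp of the ORF 3'
    boundary or overlap it.
    """
    seq = genome[element.contig]
    if orf.strand == "+":
        stop_iv = (orf.end - 3, orf.end)
        stop_codon = seq[orf.end - 3: orf.end]
        gap = element.start - orf.end
    else:
        stop_iv = (orf.start, orf.start + 3)
        stop_codon = reverse_complement(seq[orf.start: orf.start + 3])
        gap = orf.start - element.end
    if gap > 3:
        return False
    if stop_codon != "TAG" or element.tag_seq[1:4] != "TAG":
        return False
    if element.tag_at_start:
        tag_iv = (element.start, element.start + 4)
    else:
        tag_iv = (element.end - 4, element.end)
    if element.strand == "+":
        # tag reads left-to-right: TAG occupies tag positions 1-3
        tag_tag_iv = (tag_iv[0] + 1, tag_iv[1])
    else:
        # tag reads right-to-left on the minus strand
        tag_tag_iv = (tag_iv[0], tag_iv[1] - 1)
    return tag_tag_iv == stop_iv and element.strand == orf.strand


# ---------------------------------------------------------------------------
# Tyrosine transposase flanks
# ---------------------------------------------------------------------------

#: per-mismatch penalty in the arm-alignment score (match scores +1); a
#: mismatch must be paid back by several matches, which keeps reported
#: arms from absorbing flanking noise and suppresses chance alignments
MISMATCH_PENALTY = 4


def _best_window_on_diagonal(
    eq: np.ndarray, min_arm: int, max_arm: int, max_mismatch: int
):
    """Best-scoring alignment window on one diagonal, or None.

    Maximum-scoring subarray over +1/-MISMATCH_PENALTY, constrained to
    [min_arm, max_arm] bp and at most ``max_mismatch`` mismatches. Random
    sequence almost never sustains a positive score over ``min_arm``
    positions, so chance alignments fall away without a separate
    significance filter.
    """
    n = eq.size
    best = None  # (score, -length, start)
    score = 0
    left = 0
    for right in range(n):
        gain = 1 if eq[right] else -MISMATCH_PENALTY
        if score <= 0:
            score = gain
            left = right
        else:
            score += gain
        length = right - left + 1
        if length < min_arm:
            continue
        start = left
        use_len = length
        if use_len > max_arm:
            start = right + 1 - max_arm
            use_len = max_arm
        m = int((~eq[start: right + 1]).sum())
        if m > max_mismatch:
            continue
        s = (use_len - m) - MISMATCH_PENALTY * m
        key = (s, -use_len, -start)
        if best is None or key > best[0]:
            best = (key, start, use_len, m)
    return best


def find_tirs(
    genome_seq: str,
    gene: OrfRecord,
    window: int = 500,
    min_arm: int = 15,
    max_arm: int = 60,
    max_mismatch: int = 3,
    edge_overlap: int = 30,
) -> list[TirArmPair]:
    """Terminal-inverted-repeat arm pairs bracketing a gene.

    Searches ``window`` bp upstream and downstream (plus ``edge_overlap``
    bp into the gene, so arms overlapping the gene ends are found and
    flagged 5'ov/3'ov) for an upstream arm whose reverse complement
    recurs downstream with at most ``max_mismatch`` substitutions.
    """
    n = len(genome_seq)
    up_lo = max(0, gene.start - window)
    up_hi = min(n, gene.start + edge_overlap)
    down_lo = max(0, gene.end - edge_overlap)
    down_hi = min(n, gene.end + window)
    U = genome_seq[up_lo:up_hi].upper()
    D = genome_seq[down_lo:down_hi].upper()
    if len(U) < min_arm or len(D) < min_arm:
        return []
    Dp = reverse_complement(D)
    u = np.frombuffer(U.encode(), dtype="S1")
    d = np.frombuffer(Dp.encode(), dtype="S1")
    hits = []
    for c in range(-(len(U) - min_arm), len(Dp) - min_arm + 1):
        i0 = max(0, -c)
        i1 = min(len(U), len(Dp) - c)
        if i1 - i0 < min_arm:
            continue
        eq = u[i0:i1] == d[i0 + c: i1 + c]
        best = _best_window_on_diagonal(eq, min_arm, max_arm, max_mismatch)
        if best is None:
            continue
        _, start, length, mism = best
        ui = i0 + start
        ki = ui + c
        up_start = up_lo + ui
        # Dp index k maps back to D offset len(D) - length - k for a window
        down_off = len(D) - length - ki
        down_start = down_lo + down_off
        if down_start < up_start + length:
            continue  # arms must not cross
        hits.append(
            TirArmPair(
                up_start=up_start,
                up_end=up_start + length,
                down_start=down_start,
                down_end=down_start + length,
                arm_len=length,
                mismatches=mism,
                up_seq=genome_seq[up_start: up_start + length],
                down_seq=genome_seq[down_start: down_start + length],
                five_ov=up_start + length > gene.start,
                three_ov=down_start < gene.end,
            )
        )
    hits.sort(key=lambda h: (-h.arm_len, h.mismatches, h.up_start))
    chosen: list[TirArmPair] = []
    for h in hits:
        clash = any(
            min(h.up_end, c.up_end) - max(h.up_start, c.up_start) > 0
            or min(h.down_end, c.down_end) - max(h.down_start, c.down_start)
            > 0
            for c in chosen
        )
        if not clash:
            chosen.append(h)
    # best-supported pair first (longest arm, fewest mismatches)
    return chosen


def classify_gene_flanks(
    gene: OrfRecord,
    elements: list[RepElement],
    tirs: list[TirArmPair],
    window: int = 500,
) -> TirtronCall:
    """REPtron / TIRtron / none call for one transposase gene.

    REP monomers or dimers within ``window`` of the gene make a REPtron;
    TIR pairs with no REP evidence a TIRtron; REP evidence accompanied by
    TIR-like flanks is still a REPtron, with the TIRs noted (degenerate
    repeats can adjoin unrelated stem-loops into composite TIRs).
    """
    nearby = [
        el for el in elements
        if el.contig == gene.contig
        and el.end > gene.start - window
        and el.start < gene.end + window
        and not (el.start >= gene.start and el.end <= gene.end)
    ]
    up = [el for el in nearby if el.end <= gene.start + 3]
    down = [el for el in nearby if el.start >= gene.end - 3]
    dist_up = min((gene.start - el.end for el in up), default=None)
    dist_down = min((el.start - gene.end for el in down), default=None)
    if nearby:
        return TirtronCall(
            gene_id=gene.orf_id,
            kind="REPtron",
            rep_ids=tuple(el.element_id for el in nearby),
            tir_pairs=tuple(tirs),
            dist_upstream=dist_up,
            dist_downstream=dist_down,
            tir_note=bool(tirs),
        )
    if tirs:
        best = tirs[0]
        return TirtronCall(
            gene_id=gene.orf_id,
            kind="TIRtron",
            tir_pairs=tuple(tirs),
            dist_upstream=gene.start - best.up_end,
            dist_downstream=best.down_start - gene.end,
        )
    return TirtronCall(gene_id=gene.orf_id, kind="none")


def scan_motif(seq: str, motif: str = TIR_MOTIF) -> list[tuple[int, str]]:
    """All exact (degenerate) motif occurrences on both strands.

    Returns (0-based start on the forward strand, strand) pairs sorted by
    position.
    """
    s = seq.upper()
    out = []
    for strand, pattern in (
        ("+", motif),
        ("-", reverse_complement(motif)),
    ):
        rx = re.compile("(?=(" + degenerate_to_regex(pattern) + "))")
        for m in rx.finditer(s):
            out.append((m.start(), strand))
    # a self-complementary motif instance would be reported once per strand
    out.sort(key=lambda t: (t[0], t[1]))
    return out


@dataclass(frozen=True)
class _TirOccurrence:
    element_id: str
    contig: str
    start: int
    end: int
    strand: str

    @property
    def tag_at_start(self) -> bool:
        return self.strand == "+"


def _mismatch_profile(seq: str, pattern: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    pat = np.frombuffer(pattern.encode(), dtype="S1")
    if arr.size < pat.size:
        return np.empty(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(arr, pat.size)
    return (win != pat).sum(axis=1)


def tir_family_census(
    genome: dict[str, str],
    arm_seq: str,
    max_mismatch: int = 3,
    max_spacer: int = 100,
) -> dict[str, int]:
    """Genome-wide S/D/G census of a TIR arm family.

    Occurrences of the arm on either strand (up to ``max_mismatch``
    substitutions) are partitioned with the same topology rules as
    repeats: isolated copies are singletons, adjacent inverted/tandem
    pairs dimers, runs of three or more groups.
    """
    arm = arm_seq.upper()
    occ: list[_TirOccurrence] = []
    k = 0
    for contig in sorted(genome):
        seq = genome[contig].upper()
        fwd = _mismatch_profile(seq, arm)
        rev = _mismatch_profile(seq, reverse_complement(arm))
        taken: dict[int, tuple[int, str]] = {}
        for pos in np.flatnonzero(fwd <= max_mismatch):
            taken[int(pos)] = (int(fwd[pos]), "+")
        for pos in np.flatnonzero(rev <= max_mismatch):
            p = int(pos)
            if p not in taken or int(rev[pos]) < taken[p][0]:
                taken[p] = (int(rev[pos]), "-")
        # suppress overlapping shifted matches of the same copy
        last_end = -1
        for p in sorted(taken):
            if p < last_end:
                continue
            k += 1
            occ.append(
                _TirOccurrence(
                    element_id=f"tir{k:04d}",
                    contig=contig,
                    start=p,
                    end=p + len(arm),
                    strand=taken[p][1],
                )
            )
            last_end = p + len(arm)
    part = partition_elements(occ, max_spacer=max_spacer,
                              cluster_gap=max_spacer)
    return {
        "S": len(part.singletons),
        "D": len(part.dimers),
        "G": len(part.clusters),
        "total": len(occ),
    }


def contexts_to_frame(records: list[ContextRecord]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])
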