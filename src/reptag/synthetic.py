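"""Seeded synthetic genomes with planted repeat architecture.

The generator emulates the statistical structure the analysis assumes:
i.i.d. background sequence of configurable GC content carrying repeat
elements instantiated from the family catalog's degenerate consensi
(singletons, HH/TT/HT dimers with structured spacers, clusters), ORF
pairs in every orientation pattern around the planted repeats, in-frame
intragenic insertions, and tyrosine-transposase genes flanked by repeats
(REPtron geometry) or by long terminal inverted repeats (TIRtron
geometry) with optional additional arm copies. Every planted feature is
recorded in a truth table keyed to the emitted FASTA/GFF coordinates, so
the whole pipeline can be scored against construction.

Same seed, same spec -> byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import catalog as catalog_mod
from .catalog import FamilyDefinition
from .context import OrfRecord
from .seqcore import IUPAC_SETS, bases_pair, reverse_complement

GUARD = 50  # bp of background insulation around every planted feature

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS
)


class PackingError(ValueError):
    """Planted features do not fit in the requested genome length."""


# ---------------------------------------------------------------------------
# Plant specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepPlant:
    """One repeat architecture plus (optionally) its ORF context."""

    family_id: str
    architecture: str = "S"  # S | HH | TT | HT | G<n>
    spacer_len: int = 40
    mutations: tuple[int, ...] = (0,)  # per member, cycled
    context: str | None = None  # conv | div | uni | None
    orf_distances: tuple[int, int] = (20, 60)
    orf_len_aa: int = 120
    homodimer: bool = False
    hybrid_with: str | None = None  # second family for hybrid dimers
    provides_stop: bool = False
    complementary_ends: int = 0  # planted complementary spacer ends
    spacer_hairpin: bool = False  # plant a perfect SLS inside the spacer


@dataclass(frozen=True)
class IntragenicPlant:
    """Repeat(s) inserted in frame within a coding sequence."""

    family_id: str
    product_aa: int = 130  # final product length, insert included
    codon_offset: int = 40
    n_members: int = 1  # 1 = single insert, 2 = dimer insert
    spacer_len: int = 6  # dimer spacer; total insert must be in frame


@dataclass(frozen=True)
class TransposasePlant:
    """A tyrosine-transposase gene with REP or TIR flanks."""

    flank: str = "rep_dimer"  # rep_monomer | rep_dimer | tir | none
    family_id: str | None = None
    gene_len_aa: int = 150
    distances: tuple[int, int] = (60, 60)
    tir_arm_len: int = 20
    # extra genome-wide copies of the TIR arm: architectures S, D (inverted
    # pair) or G<n> (tandem run), planted downstream within the cassette
    tir_extra: tuple[str, ...] = ()


@dataclass(frozen=True)
class OrfPlant:
    length_aa: int = 150
    strand: str = "+"


@dataclass(frozen=True)
class GenomeSpec:
    length: int = 100_000
    gc: float = 0.5
    seed: int = 0
    name: str = "synthetic_contig"
    reps: tuple[RepPlant, ...] = ()
    intragenics: tuple[IntragenicPlant, ...] = ()
    transposases: tuple[TransposasePlant, ...] = ()
    orfs: tuple[OrfPlant, ...] = ()


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    orfs: list[OrfRecord]
    truth: pd.DataFrame
    spec: GenomeSpec

    def emit(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fasta"
        with open(fasta, "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i: i + 70] + "\n")
        gff = outdir / "annotations.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for o in self.orfs:
                attrs = (
                    f"ID={o.orf_id};product={o.annotation};"
                    f"product_length={o.product_len_aa}"
                )
                fh.write(
                    "\t".join(
                        [o.contig, "reptag_sim", "CDS", str(o.start + 1),
                         str(o.end), ".", o.strand, "0", attrs]
                    ) + "\n"
                )
        truth = outdir / "truth.tsv"
        self.truth.to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "gff3": gff, "truth": truth}


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Resolve each degenerate position uniformly over its allowed bases."""
    out = []
    for c in consensus.upper():
        options = sorted(IUPAC_SETS[c])
        out.append(options[rng.integers(len(options))] if len(options) > 1
                   else options[0])
    return "".join(out)


def random_background(rng: np.random.Generator, length: int,
                      gc: float) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    bases = np.array(list("ATGC"))[rng.choice(4, size=length, p=p)]
    return "".join(bases)


def _sample_loop(defn: FamilyDefinition, rng: np.random.Generator,
                 loop_len: int | None = None) -> str:
    if defn.loop_consensus is not None:
        return instantiate_consensus(defn.loop_consensus, rng)
    lo, hi = defn.loop_range
    if defn.loop_classes:
        left, right = defn.loop_classes[
            rng.integers(len(defn.loop_classes))
        ]
        min_len = max(lo, len(left) + len(right))
        n = loop_len if loop_len is not None else int(
            rng.integers(min_len, hi + 1)
        )
        interior = random_background(rng, n - len(left) - len(right), 0.5)
        return (instantiate_consensus(left, rng) + interior
                + instantiate_consensus(right, rng))
    n = loop_len if loop_len is not None else int(rng.integers(lo, hi + 1))
    return random_background(rng, n, 0.5)


@dataclass
class _BuiltElement:
    seq: str  # element-strand sequence
    family_id: str
    tag: str
    extra: str
    arm5: str
    loop: str
    arm3: str
    tail: str
    mutations: int


def build_element(
    defn: FamilyDefinition,
    rng: np.random.Generator,
    mutations: int = 0,
    loop_len: int | None = None,
) -> _BuiltElement:
    """Instantiate one concrete element from a family consensus.

    The right arm starts as the exact reverse complement of the sampled
    left arm; the requested number of substitutions is then applied to
    arm positions, each chosen to violate both the arm consensus and
    stem pairing (wobble included), so one mutation costs exactly one
    consensus mismatch and one unpaired stem position.
    """
    tag = instantiate_consensus(defn.tag, rng)
    extra = instantiate_consensus(defn.extra_bases, rng) \
        if defn.extra_bases else ""
    arm_cons = defn.arms[int(rng.integers(len(defn.arms)))]
    arm5 = instantiate_consensus(arm_cons, rng)
    loop = _sample_loop(defn, rng, loop_len=loop_len)
    arm3 = reverse_complement(arm5)
    tail = instantiate_consensus(defn.tail, rng) if defn.tail else ""
    arm5_l, arm3_l = list(arm5), list(arm3)
    L = len(arm5)
    pair_idx = rng.permutation(L)[:mutations]
    arm3_cons = reverse_complement(arm_cons)
    for i in pair_idx:
        on_left = bool(rng.integers(2))
        if on_left:
            orig = arm5_l[i]
            partner = arm3_l[L - 1 - i]
            cons_set = IUPAC_SETS[arm_cons[i]]
        else:
            orig = arm3_l[L - 1 - i]
            partner = arm5_l[i]
            cons_set = IUPAC_SETS[arm3_cons[L - 1 - i]]
        choices = [
            b for b in "ACGT"
            if b != orig and b not in cons_set
            and not bases_pair(b, partner, allow_wobble=True)
        ]
        if not choices:  # fall back: break the consensus at least
            choices = [b for b in "ACGT" if b != orig and b not in cons_set]
        new = choices[int(rng.integers(len(choices)))]
        if on_left:
            arm5_l[i] = new
        else:
            arm3_l[L - 1 - i] = new
    arm5, arm3 = "".join(arm5_l), "".join(arm3_l)
    return _BuiltElement(
        seq=tag + extra + arm5 + loop + arm3 + tail,
        family_id=defn.family_id,
        tag=tag, extra=extra, arm5=arm5, loop=loop, arm3=arm3, tail=tail,
        mutations=int(mutations),
    )


def build_orf(rng: np.random.Generator, length_aa: int,
              stop: str = "TAA", last_sense: str | None = None) -> str:
    """A CDS of ``length_aa`` codons plus stop: ATG, sense codons, stop."""
    codons = ["ATG"]
    for _ in range(length_aa - 2):
        codons.append(_SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))])
    if length_aa >= 2:
        codons.append(
            last_sense
            if last_sense is not None
            else _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        )
    codons.append(stop)
    return "".join(codons)


# ---------------------------------------------------------------------------
# Cassette assembly
# ---------------------------------------------------------------------------

@dataclass
class _Feature:
    kind: str  # rep | orf | gene | tir_arm
    rel_start: int
    rel_end: int
    strand: str
    meta: dict = field(default_factory=dict)


@dataclass
class _Cassette:
    seq: str
    features: list[_Feature]


def _spacer_seq(rng, length: int, comp_ends: int, hairpin: bool,
                gc: float) -> str:
    sp = list(random_background(rng, length, gc))
    if comp_ends:
        k = min(comp_ends, length // 2)
        for i in range(k):
            sp[length - 1 - i] = reverse_complement(sp[i])
        if 2 * k < length:  # stop the complementary run exactly at k
            a = sp[k]
            b = sp[length - 1 - k]
            if bases_pair(a, b, allow_wobble=False):
                sp[length - 1 - k] = a  # identical bases never pair
    if hairpin and length >= 16:
        arm = random_background(rng, 5, 0.6)
        mid = length // 2 - 6
        hp = arm + "TTT" + reverse_complement(arm)
        sp[mid: mid + len(hp)] = list(hp)
    return "".join(sp)


def _rep_cassette(plant: RepPlant, cat: dict[str, FamilyDefinition],
                  rng: np.random.Generator, gc: float) -> _Cassette:
    arch = plant.architecture
    if arch == "S":
        n_members, strands = 1, ["+"]
    elif arch == "HH":
        n_members, strands = 2, ["+", "-"]
    elif arch == "TT":
        n_members, strands = 2, ["-", "+"]
    elif arch == "HT":
        n_members, strands = 2, ["+", "+"]
    elif arch.startswith("G"):
        n_members = int(arch[1:])
        strands = [("+", "-")[i % 2] for i in range(n_members)]
    else:
        raise ValueError(f"unknown architecture {arch!r}")

    members: list[_BuiltElement] = []
    for i in range(n_members):
        fam = plant.hybrid_with if (plant.hybrid_with and i == 1) \
            else plant.family_id
        mut = plant.mutations[i % len(plant.mutations)]
        if plant.homodimer and i > 0:
            members.append(members[0])
        else:
            members.append(build_element(cat[fam], rng, mutations=mut))

    parts: list[str] = []
    features: list[_Feature] = []
    pos = 0

    up_orf = down_orf = None
    overlap = 0
    if plant.context is not None:
        up_strand, down_strand = {
            "conv": ("+", "-"),
            "div": ("-", "+"),
            "uni": ("+", "+"),
        }[plant.context]
        if plant.provides_stop:
            up_cds = build_orf(rng, plant.orf_len_aa, stop="TAG",
                               last_sense="GGG")
        else:
            up_cds = build_orf(rng, plant.orf_len_aa)
        up_seq = up_cds if up_strand == "+" else reverse_complement(up_cds)
        up_orf = _Feature("orf", 0, len(up_seq), up_strand,
                          {"product_aa": plant.orf_len_aa})
        parts.append(up_seq)
        pos = len(up_seq)
        features.append(up_orf)
        if plant.provides_stop:
            overlap = 4  # element tag overlaps the ORF's trailing G+TAG
        else:
            gap = plant.orf_distances[0]
            parts.append(random_background(rng, gap, gc))
            pos += gap

    member_feats = []
    for i, built in enumerate(members):
        if i > 0:
            sp = _spacer_seq(rng, plant.spacer_len,
                             plant.complementary_ends, plant.spacer_hairpin,
                             gc)
            parts.append(sp)
            pos += plant.spacer_len
        gseq = built.seq if strands[i] == "+" \
            else reverse_complement(built.seq)
        if overlap and i == 0:
            gseq = gseq[overlap:]
            start = pos - overlap
        else:
            start = pos
        parts.append(gseq)
        pos = start + len(built.seq)
        feat = _Feature(
            "rep", start, pos, strands[i],
            {
                "family_id": built.family_id,
                "arm5": built.arm5, "loop": built.loop, "arm3": built.arm3,
                "tag": built.tag, "mutations": built.mutations,
                "member_index": i,
                "architecture": arch,
                "role": {"S": "S"}.get(arch, "D" if n_members == 2 else "G"),
                "provides_stop": plant.provides_stop and i == 0,
                "context": plant.context or "",
                "spacer_len": plant.spacer_len if n_members > 1 else "",
                "complementary_ends": plant.complementary_ends,
            },
        )
        features.append(feat)
        member_feats.append(feat)

    if n_members == 2:
        a, b = member_feats
        same_body = (
            members[0].arm5 == members[1].arm5
            and members[0].loop == members[1].loop
            and members[0].arm3 == members[1].arm3
        )
        if members[0].family_id != members[1].family_id:
            comp = "hybrid"
        elif same_body:
            comp = "homodimer"
        else:
            comp = "heterodimer"
        for f in member_feats:
            f.meta["composition"] = comp

    if plant.context is not None:
        gap = plant.orf_distances[1]
        parts.append(random_background(rng, gap, gc))
        pos += gap
        down_cds = build_orf(rng, plant.orf_len_aa)
        down_seq = down_cds if down_strand == "+" \
            else reverse_complement(down_cds)
        down_orf = _Feature("orf", pos, pos + len(down_seq), down_strand,
                            {"product_aa": plant.orf_len_aa})
        parts.append(down_seq)
        pos += len(down_seq)
        features.append(down_orf)
        for f in member_feats:
            f.meta["dist_upstream"] = max(0, f.rel_start - up_orf.rel_end)
            f.meta["dist_downstream"] = max(0, down_orf.rel_start - f.rel_end)

    return _Cassette("".join(parts), features)


def _intragenic_cassette(plant: IntragenicPlant,
                         cat: dict[str, FamilyDefinition],
                         rng: np.random.Generator, gc: float) -> _Cassette:
    defn = cat[plant.family_id]
    for _attempt in range(200):
        sub = np.random.default_rng(rng.integers(2**31))
        inserts = [build_element(defn, sub) for _ in range(plant.n_members)]
        pieces = []
        for i, b in enumerate(inserts):
            if i > 0:
                pieces.append(random_background(sub, plant.spacer_len, gc))
            pieces.append(b.seq)
        insert = "".join(pieces)
        if len(insert) % 3 != 0:
            raise ValueError(
                f"intragenic insert for {plant.family_id} is {len(insert)} "
                "bp, not a codon multiple; adjust spacer_len"
            )
        base_aa = plant.product_aa - len(insert) // 3
        if base_aa < plant.codon_offset + 2:
            raise ValueError("codon_offset beyond ORF length")
        cds = build_orf(sub, base_aa)
        at = 3 * plant.codon_offset
        cds = cds[:at] + insert + cds[at:]
        codons = [cds[i: i + 3] for i in range(0, len(cds) - 3, 3)]
        if any(c in _STOPS for c in codons):
            continue
        features = [
            _Feature("orf", 0, len(cds), "+",
                     {"product_aa": plant.product_aa})
        ]
        pos = at
        peptide_all = str(Seq(insert).translate(table=11)) \
            if len(inserts) else ""
        for i, b in enumerate(inserts):
            if i > 0:
                pos += plant.spacer_len
            start = pos
            pos += len(b.seq)
            off_start = start
            off_end = pos
            first = math.ceil(off_start / 3)
            last = off_end // 3
            peptide = str(Seq(cds[first * 3: last * 3]).translate(table=11))
            features.append(
                _Feature(
                    "rep", start, pos, "+",
                    {
                        "family_id": b.family_id,
                        "arm5": b.arm5, "loop": b.loop, "arm3": b.arm3,
                        "tag": b.tag, "mutations": 0,
                        "member_index": i,
                        "architecture": "S" if plant.n_members == 1
                        else "HT",
                        "role": "S" if plant.n_members == 1 else "D",
                        "context": "intragenic",
                        "peptide": peptide,
                        "region": "",
                        "provides_stop": False,
                    },
                )
            )
        return _Cassette(cds, features)
    raise RuntimeError("could not build a stop-free intragenic insertion")


def _transposase_cassette(plant: TransposasePlant,
                          cat: dict[str, FamilyDefinition],
                          rng: np.random.Generator, gc: float,
                          isolation: int = 520) -> _Cassette:
    from .context import TIR_MOTIF

    # gene CDS with a planted GGGGWSAS motif, stop-free
    for _attempt in range(200):
        sub = np.random.default_rng(rng.integers(2**31))
        cds = build_orf(sub, plant.gene_len_aa)
        motif = instantiate_consensus(TIR_MOTIF, sub)
        at = 90
        trial = cds[:at] + motif + cds[at + len(motif):]
        codons = [trial[i: i + 3] for i in range(0, len(trial) - 3, 3)]
        if not any(c in _STOPS for c in codons):
            cds = trial
            break
    else:
        raise RuntimeError("could not plant a stop-free transposase motif")

    parts: list[str] = [random_background(rng, isolation, gc)]
    pos = isolation
    features: list[_Feature] = []
    d_up, d_down = plant.distances

    def add_rep(arch: str):
        nonlocal pos
        fam = cat[plant.family_id]
        if arch == "dimer":
            e1 = build_element(fam, rng)
            e2 = build_element(fam, rng)
            sp = random_background(rng, 30, gc)
            for built, strand, seq in (
                (e1, "+", e1.seq),
                (None, None, sp),
                (e2, "-", reverse_complement(e2.seq)),
            ):
                if built is None:
                    parts.append(seq)
                    pos += len(seq)
                    continue
                parts.append(seq)
                features.append(
                    _Feature("rep", pos, pos + len(seq), strand, {
                        "family_id": built.family_id,
                        "arm5": built.arm5, "loop": built.loop,
                        "arm3": built.arm3, "tag": built.tag,
                        "mutations": 0, "member_index": 0,
                        "architecture": "HH", "role": "D",
                        "context": "", "provides_stop": False,
                    })
                )
                pos += len(seq)
        else:
            e = build_element(fam, rng)
            parts.append(e.seq)
            features.append(
                _Feature("rep", pos, pos + len(e.seq), "+", {
                    "family_id": e.family_id,
                    "arm5": e.arm5, "loop": e.loop, "arm3": e.arm3,
                    "tag": e.tag, "mutations": 0, "member_index": 0,
                    "architecture": "S", "role": "S",
                    "context": "", "provides_stop": False,
                })
            )
            pos += len(e.seq)

    def clamp_last():
        # 'A' cannot pair 'A': clamping the bases flanking both TIR arms
        # to A stops the inverted repeat from extending by chance, so the
        # planted arm length is exactly maximal
        parts[-1] = parts[-1][:-1] + "A"

    tir_arm = None
    if plant.flank in ("rep_monomer", "rep_dimer"):
        add_rep("dimer" if plant.flank == "rep_dimer" else "monomer")
    elif plant.flank == "tir":
        tir_arm = random_background(rng, plant.tir_arm_len, 0.5)
        clamp_last()
        parts.append(tir_arm)
        features.append(
            _Feature("tir_arm", pos, pos + len(tir_arm), "+",
                     {"arm_seq": tir_arm, "side": "up"})
        )
        pos += len(tir_arm)

    gap_up = random_background(rng, d_up, gc)
    if plant.flank == "tir":
        gap_up = "A" + gap_up[1:]
    parts.append(gap_up)
    pos += d_up
    gene = _Feature("gene", pos, pos + len(cds), "+",
                    {"product_aa": plant.gene_len_aa,
                     "gene_kind": {"rep_monomer": "REPtron",
                                   "rep_dimer": "REPtron",
                                   "tir": "TIRtron",
                                   "none": "none"}[plant.flank],
                     "motif": True})
    parts.append(cds)
    features.append(gene)
    pos += len(cds)
    gap_down = random_background(rng, d_down, gc)
    if plant.flank == "tir":
        gap_down = gap_down[:-1] + "A"
    parts.append(gap_down)
    pos += d_down

    if plant.flank in ("rep_monomer", "rep_dimer"):
        add_rep("monomer")
    elif plant.flank == "tir":
        down = reverse_complement(tir_arm)
        parts.append(down)
        features.append(
            _Feature("tir_arm", pos, pos + len(down), "-",
                     {"arm_seq": tir_arm, "side": "down"})
        )
        pos += len(down)
        parts.append("A")  # outer clamp, paired against the upstream 'A'
        pos += 1
        for arch in plant.tir_extra:
            gap = 300  # beyond the pairing threshold: isolates each plant
            parts.append(random_background(rng, gap, gc))
            pos += gap
            if arch == "S":
                copies = [("+", 0)]
            elif arch == "D":
                copies = [("+", 0), ("-", 40)]
            elif arch.startswith("G"):
                copies = [(("+", "-")[i % 2], 40 if i else 0)
                          for i in range(int(arch[1:]))]
            else:
                raise ValueError(f"unknown TIR architecture {arch!r}")
            for strand, pregap in copies:
                if pregap:
                    parts.append(random_background(rng, pregap, gc))
                    pos += pregap
                seq = tir_arm if strand == "+" \
                    else reverse_complement(tir_arm)
                parts.append(seq)
                features.append(
                    _Feature("tir_arm", pos, pos + len(seq), strand,
                             {"arm_seq": tir_arm, "side": "extra",
                              "architecture": arch})
                )
                pos += len(seq)

    parts.append(random_background(rng, isolation, gc))
    return _Cassette("".join(parts), features)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def _disambiguate_flanks(
    genome_seq: str,
    truth_rows: list[dict],
    orfs,
    catalog: list[FamilyDefinition],
) -> str:
    """Remove accidental opposite-strand parses of planted elements.

    A planted element is almost palindromic, so if the 4 background bases
    beyond its tail end happen to read as a tag on the opposite strand the
    locus acquires a second, equally valid interpretation and the truth
    table would no longer be unique. Such chance 4-mers (in background or
    plain spacer sequence only — never inside another planted feature or
    ORF) are rewritten to match no tag in either orientation.
    """
    tags = [t for d in catalog for t in d.all_tags]

    def hits_tag(mer: str) -> bool:
        return any(
            all(b in IUPAC_SETS[c] for b, c in zip(mer, t)) for t in tags
        ) or any(
            all(b in IUPAC_SETS[c]
                for b, c in zip(reverse_complement(mer), t))
            for t in tags
        )

    reserved = [(int(r["start"]), int(r["end"])) for r in truth_rows]
    reserved += [(o.start, o.end) for o in orfs]
    seq = list(genome_seq)
    n = len(seq)
    for r in truth_rows:
        if r.get("kind") != "rep":
            continue
        if r["strand"] == "+":
            zone = (int(r["end"]), int(r["end"]) + 4)
        else:
            zone = (int(r["start"]) - 4, int(r["start"]))
        if zone[0] < 0 or zone[1] > n:
            continue
        if any(zone[0] < e and zone[1] > s for s, e in reserved):
            continue
        mer = "".join(seq[zone[0]: zone[1]])
        if not hits_tag(mer):
            continue
        fixed = None
        for i in range(4):
            for b in "ACGT":
                if b == mer[i]:
                    continue
                trial = mer[:i] + b + mer[i + 1:]
                if not hits_tag(trial):
                    fixed = trial
                    break
            if fixed:
                break
        if fixed:
            seq[zone[0]: zone[1]] = list(fixed)
    return "".join(seq)


def generate_genome(spec: GenomeSpec,
                    catalog: list[FamilyDefinition] | None = None
                    ) -> SyntheticGenome:
    """Assemble the genome, annotations and truth table for a spec."""
    if catalog is None:
        catalog = catalog_mod.load_catalog()
    cat = {d.family_id: d for d in catalog}
    rng = np.random.default_rng(spec.seed)

    cassettes: list[_Cassette] = []
    for plant in spec.reps:
        cassettes.append(_rep_cassette(plant, cat, rng, spec.gc))
    for plant in spec.intragenics:
        cassettes.append(_intragenic_cassette(plant, cat, rng, spec.gc))
    for plant in spec.transposases:
        cassettes.append(_transposase_cassette(plant, cat, rng, spec.gc))
    for plant in spec.orfs:
        cds = build_orf(rng, plant.length_aa)
        seq = cds if plant.strand == "+" else reverse_complement(cds)
        cassettes.append(
            _Cassette(seq, [_Feature("orf", 0, len(seq), plant.strand,
                                     {"product_aa": plant.length_aa})])
        )

    total = sum(len(c.seq) for c in cassettes)
    n_gaps = len(cassettes) + 1
    free = spec.length - total
    if free < n_gaps * GUARD:
        raise PackingError(
            f"planted features span {total} bp; genome length {spec.length} "
            f"bp cannot host them with {GUARD} bp guards"
        )
    extra = free - n_gaps * GUARD
    shares = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [GUARD + int(s) for s in shares]

    parts: list[str] = []
    placed: list[tuple[int, _Cassette]] = []
    pos = 0
    for gap, cassette in zip(gaps, cassettes):
        parts.append(random_background(rng, gap, spec.gc))
        pos += gap
        placed.append((pos, cassette))
        parts.append(cassette.seq)
        pos += len(cassette.seq)
    parts.append(random_background(rng, gaps[-1], spec.gc))
    genome_seq = "".join(parts)
    assert len(genome_seq) == spec.length

    orfs: list[OrfRecord] = []
    truth_rows: list[dict] = []
    counters = {"orf": 0, "rep": 0, "gene": 0, "tir": 0}
    for offset, cassette in placed:
        for f in cassette.features:
            start = offset + f.rel_start
            end = offset + f.rel_end
            if f.kind in ("orf", "gene"):
                counters["orf"] += 1
                oid = f"orf{counters['orf']:04d}"
                product = ("tyrosine transposase" if f.kind == "gene"
                           else "hypothetical protein")
                orfs.append(
                    OrfRecord(
                        orf_id=oid, contig=spec.name, start=start, end=end,
                        strand=f.strand,
                        product_len_aa=f.meta["product_aa"],
                        annotation=product,
                    )
                )
                if f.kind == "gene":
                    counters["gene"] += 1
                    truth_rows.append({
                        "feature_id": oid, "kind": "transposase_gene",
                        "family_id": "", "start": start, "end": end,
                        "strand": f.strand,
                        "gene_kind": f.meta["gene_kind"],
                    })
            elif f.kind == "rep":
                counters["rep"] += 1
                rid = f"truth_rep{counters['rep']:04d}"
                row = {
                    "feature_id": rid, "kind": "rep",
                    "family_id": f.meta["family_id"],
                    "start": start, "end": end, "strand": f.strand,
                    "architecture": f.meta.get("architecture", "S"),
                    "role": f.meta.get("role", "S"),
                    "member_index": f.meta.get("member_index", 0),
                    "mutations": f.meta.get("mutations", 0),
                    "arm5": f.meta.get("arm5", ""),
                    "loop": f.meta.get("loop", ""),
                    "composition": f.meta.get("composition", ""),
                    "context": f.meta.get("context", ""),
                    "dist_upstream": f.meta.get("dist_upstream", ""),
                    "dist_downstream": f.meta.get("dist_downstream", ""),
                    "provides_stop": f.meta.get("provides_stop", False),
                    "peptide": f.meta.get("peptide", ""),
                    "spacer_len": f.meta.get("spacer_len", ""),
                    "complementary_ends": f.meta.get(
                        "complementary_ends", 0),
                    "gene_kind": "",
                }
                truth_rows.append(row)
            elif f.kind == "tir_arm":
                counters["tir"] += 1
                truth_rows.append({
                    "feature_id": f"truth_tir{counters['tir']:04d}",
                    "kind": "tir_arm", "family_id": "",
                    "start": start, "end": end, "strand": f.strand,
                    "arm5": f.meta["arm_seq"],
                    "architecture": f.meta.get("architecture",
                                               f.meta.get("side", "")),
                    "gene_kind": "",
                })
    orfs.sort(key=lambda o: (o.contig, o.start))
    genome_seq = _disambiguate_flanks(genome_seq, truth_rows, orfs, catalog)
    truth = pd.DataFrame(truth_rows)
    return SyntheticGenome(
        genome={spec.name: genome_seq}, orfs=orfs, truth=truth, spec=spec
    )


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------

#: families exercised by the default study conditions
DEFAULT_FAMILIES = [
    "GTAG-1", "GTAG-3", "GTAG-7", "GTAG-9", "GTAG-14", "GTAG-15",
    "GTAG-24", "CGTC-1", "CGTC-2", "CGTC-3", "CGTC-4",
]


def default_genome_spec(seed: int, length: int = 100_000) -> GenomeSpec:
    """The canonical desk-scale genome: ~55 planted elements in 100 kb.

    Singletons, dimers of all three topologies (including a forced
    homodimer and a hybrid), clusters of 3-5, intragenic inserts, a
    stop-codon-sharing element, one REPtron and one TIRtron, with
    per-element mutation counts alternating 0/1.
    """
    fams = DEFAULT_FAMILIES
    contexts = ["conv", "div", "uni"]
    reps: list[RepPlant] = []
    for i in range(18):
        reps.append(
            RepPlant(
                family_id=fams[i % len(fams)],
                architecture="S",
                mutations=(i % 2,),
                context=contexts[i % 3],
                orf_distances=(10 + 5 * (i % 4), 30 + 10 * (i % 5)),
            )
        )
    topos = ["HH", "TT", "HT"]
    for i in range(9):
        reps.append(
            RepPlant(
                family_id=fams[(i + 3) % len(fams)],
                architecture=topos[i % 3],
                spacer_len=(25 + 7 * i) if i % 3 else 3,
                mutations=(i % 2, 0),
                context=contexts[(i + 1) % 3],
                homodimer=(i == 4),
                complementary_ends=6 if i == 2 else 0,
                spacer_hairpin=(i == 5),
            )
        )
    # one hybrid dimer: counted as two singletons in the family census
    reps.append(
        RepPlant(
            family_id="GTAG-7", hybrid_with="GTAG-9", architecture="HH",
            spacer_len=30, mutations=(0, 0), context="uni",
        )
    )
    for i, size in enumerate((3, 4, 5)):
        reps.append(
            RepPlant(
                family_id=fams[(2 * i) % len(fams)],
                architecture=f"G{size}",
                spacer_len=35, mutations=(0, 1),
                context=contexts[i % 3],
            )
        )
    # stop-codon sharing singleton (GTAG tag supplies the ORF's TAG stop)
    reps.append(
        RepPlant(
            family_id="GTAG-7", architecture="S", context="uni",
            provides_stop=True, mutations=(0,),
        )
    )
    intragenics = (
        IntragenicPlant("CGTC-1", product_aa=130, codon_offset=40),
        IntragenicPlant("CGTC-1", product_aa=141, codon_offset=60,
                        n_members=2, spacer_len=6),
    )
    transposases = (
        TransposasePlant(flank="rep_dimer", family_id="GTAG-1",
                         distances=(60, 45)),
        TransposasePlant(flank="tir", distances=(80, 60),
                         tir_extra=("S", "D", "G3")),
    )
    orfs = tuple(OrfPlant(length_aa=110 + 10 * i, strand="+-"[i % 2])
                 for i in range(4))
    return GenomeSpec(
        length=length, gc=0.5, seed=seed,
        reps=tuple(reps), intragenics=intragenics,
        transposases=transposases, orfs=orfs,
    )
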