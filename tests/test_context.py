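"""ORF context, intragenic calls, stop sharing, TIRs and gene flanks."""

import numpy as np
import pytest

from reptag.context import (
    OrfRecord,
    classify_all_contexts,
    classify_context,
    classify_gene_flanks,
    find_intragenic,
    find_tirs,
    provides_stop,
    scan_motif,
    tir_family_census,
)
from reptag.detect import RepElement
from reptag.seqcore import reverse_complement
from reptag.synthetic import (
    GenomeSpec,
    IntragenicPlant,
    generate_genome,
    random_background,
)


def make_el(eid, start, end, strand="+", family="GTAG-7", tag="GTAG",
            contig="c1"):
    return RepElement(
        element_id=eid, contig=contig, start=start, end=end, strand=strand,
        family_id=family, tag_seq=tag, extra_seq="", arm5_seq="GGAGCAAC",
        loop_seq="TC", arm3_seq=reverse_complement("GGAGCAAC"),
        tail_seq="", stem_mismatches=0, consensus_mismatches=0,
        wobble_pairs=0,
    )


def orf(oid, start, end, strand, aa=200, note="hypothetical protein"):
    return OrfRecord(orf_id=oid, contig="c1", start=start, end=end,
                     strand=strand, product_len_aa=aa, annotation=note)


class TestIntergenicContext:
    def test_convergent_flanks(self):
        orfs = [orf("A", 600, 1000, "+"), orf("B", 1100, 1500, "-")]
        rec = classify_context(make_el("e", 1020, 1060), orfs)
        assert rec.category == "conv"
        assert (rec.dist_upstream, rec.dist_downstream) == (20, 40)
        # both facing boundaries are the ORFs' 3' ends
        assert rec.upstream_boundary == "3'"
        assert rec.downstream_boundary == "3'"

    def test_unidirectional_flanks(self):
        orfs = [orf("A", 600, 1000, "+"), orf("B", 1100, 1500, "+")]
        rec = classify_context(make_el("e", 1020, 1060), orfs)
        assert rec.category == "uni"
        assert rec.upstream_boundary == "3'"
        assert rec.downstream_boundary == "5'"

    def test_divergent_flanks(self):
        orfs = [orf("A", 600, 1000, "-"), orf("B", 1100, 1500, "+")]
        rec = classify_context(make_el("e", 1020, 1060), orfs)
        assert rec.category == "div"

    def test_missing_flank_is_contig_edge(self):
        orfs = [orf("B", 1100, 1500, "+")]
        rec = classify_context(make_el("e", 1020, 1060), orfs)
        assert rec.category == "contig_edge"

    def test_adjacent_orf_distance_zero(self):
        orfs = [orf("A", 600, 1020, "+"), orf("B", 1100, 1500, "-")]
        rec = classify_context(make_el("e", 1020, 1060), orfs)
        assert rec.dist_upstream == 0


class TestIntragenicFilter:
    @staticmethod
    def _syn(product_aa, codon_offset=40, n=1, spacer=6):
        spec = GenomeSpec(
            length=4000, seed=3,
            intragenics=(IntragenicPlant("CGTC-1", product_aa=product_aa,
                                         codon_offset=codon_offset,
                                         n_members=n, spacer_len=spacer),),
        )
        return generate_genome(spec)

    def test_threshold_inclusive_at_120(self, catalog):
        syn = self._syn(121)
        row = syn.truth[syn.truth["kind"] == "rep"].iloc[0]
        el = make_el("e", int(row.start), int(row.end), family="CGTC-1",
                     tag="CGTC", contig=syn.spec.name)
        recs = find_intragenic([el], syn.orfs, syn.genome)
        assert len(recs) == 1 and recs[0].category == "intragenic"

    def test_short_hypothetical_orfs_excluded(self, catalog):
        syn = self._syn(119)
        row = syn.truth[syn.truth["kind"] == "rep"].iloc[0]
        el = make_el("e", int(row.start), int(row.end), family="CGTC-1",
                     tag="CGTC", contig=syn.spec.name)
        assert find_intragenic([el], syn.orfs, syn.genome) == []
        # and the filter is tunable
        assert len(find_intragenic([el], syn.orfs, syn.genome,
                                   min_aa=100)) == 1

    def test_dimer_insert_encodes_twenty_aa(self):
        """A 60 bp in-frame dimer insert encodes 20 amino acids."""
        from Bio.Seq import Seq

        syn = self._syn(141, codon_offset=60, n=2, spacer=6)
        rows = syn.truth[syn.truth["kind"] == "rep"]
        assert len(rows) == 2
        start = int(rows.start.min())
        end = int(rows.end.max())
        assert end - start == 60
        insert = syn.genome[syn.spec.name][start:end]
        peptide = str(Seq(insert).translate(table=11))
        assert len(peptide) == 20
        assert "*" not in peptide
        # per-member encoded peptides are the in-frame pieces of it
        els = [make_el(f"e{i}", int(r.start), int(r.end), family="CGTC-1",
                       tag="CGTC", contig=syn.spec.name)
               for i, r in enumerate(rows.itertuples())]
        recs = find_intragenic(els, syn.orfs, syn.genome)
        assert [r.encoded_peptide for r in recs] == \
            [peptide[:9], peptide[11:]]

    def test_region_labels(self):
        near_start = self._syn(130, codon_offset=5)
        row = near_start.truth[near_start.truth["kind"] == "rep"].iloc[0]
        el = make_el("e", int(row.start), int(row.end), family="CGTC-1",
                     tag="CGTC", contig=near_start.spec.name)
        rec = find_intragenic([el], near_start.orfs, near_start.genome)[0]
        assert rec.region == "NH2"
        near_end = self._syn(130, codon_offset=118)
        row = near_end.truth[near_end.truth["kind"] == "rep"].iloc[0]
        el = make_el("e", int(row.start), int(row.end), family="CGTC-1",
                     tag="CGTC", contig=near_end.spec.name)
        rec = find_intragenic([el], near_end.orfs, near_end.genome)[0]
        assert rec.region == "COOH"

    def test_intragenic_takes_precedence(self):
        syn = self._syn(130)
        row = syn.truth[syn.truth["kind"] == "rep"].iloc[0]
        el = make_el("e", int(row.start), int(row.end), family="CGTC-1",
                     tag="CGTC", contig=syn.spec.name)
        recs = classify_all_contexts([el], syn.orfs, syn.genome)
        assert recs[0].category == "intragenic"


class TestProvidesStop:
    def _genome(self, stop="TAG"):
        # 10-codon ORF ending ...GGG <stop>, element tag overlapping it
        cds = "ATG" + "GCA" * 7 + "GGG" + stop
        seq = cds + "GGAGCAACTC" + "GTTGCTCC" + "C" * 40
        return {"c1": seq}, OrfRecord("A", "c1", 0, 30, "+", 9, "x")

    def test_tag_supplies_stop(self):
        genome, o = self._genome("TAG")
        el = make_el("e", 26, 48)  # tag GTAG occupies 26-30
        assert provides_stop(el, o, genome) is True

    def test_taa_stop_not_shared(self):
        genome, o = self._genome("TAA")
        el = make_el("e", 26, 48)
        assert provides_stop(el, o, genome) is False

    def test_distant_element_not_considered(self):
        genome, o = self._genome("TAG")
        el = make_el("e", 80, 102)
        assert provides_stop(el, o, genome) is False


def _tir_genome(mismatches=0, with_downstream=True, seed=5):
    rng = np.random.default_rng(seed)
    bg = list(random_background(rng, 1300, 0.5))
    arm = random_background(rng, 20, 0.5)
    up = list(arm)
    if mismatches:
        # central substitutions so trimming cannot remove them
        for i in (9, 12)[:mismatches]:
            up[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[up[i]]
    bg[520:540] = up
    if with_downstream:
        bg[760:780] = list(reverse_complement(arm))
    # clamp flanks so the planted arms are exactly maximal
    for i in (519, 540, 759, 780):
        bg[i] = "A"
    return "".join(bg), OrfRecord("g1", "c1", 600, 700, "+", 32,
                                  "tyrosine transposase")


class TestFindTirs:
    def test_exact_pair_found(self):
        seq, gene = _tir_genome()
        tirs = find_tirs(seq, gene)
        assert len(tirs) == 1
        t = tirs[0]
        assert (t.up_start, t.up_end) == (520, 540)
        assert (t.down_start, t.down_end) == (760, 780)
        assert t.mismatches == 0
        assert t.down_seq == reverse_complement(t.up_seq)

    def test_substituted_pair_reports_mismatches(self):
        seq, gene = _tir_genome(mismatches=2)
        tirs = find_tirs(seq, gene)
        assert len(tirs) == 1
        assert tirs[0].mismatches == 2
        assert tirs[0].arm_len == 20

    def test_no_downstream_arm_no_pair(self):
        seq, gene = _tir_genome(with_downstream=False)
        assert find_tirs(seq, gene) == []


class TestGeneFlanks:
    def test_rep_flanks_make_reptron(self):
        seq, gene = _tir_genome(with_downstream=False)
        els = [make_el("r1", 530, 552), make_el("r2", 740, 762)]
        call = classify_gene_flanks(gene, els, [])
        assert call.kind == "REPtron"
        assert set(call.rep_ids) == {"r1", "r2"}

    def test_tir_only_makes_tirtron(self):
        seq, gene = _tir_genome()
        tirs = find_tirs(seq, gene)
        call = classify_gene_flanks(gene, [], tirs)
        assert call.kind == "TIRtron"
        assert call.tir_pairs

    def test_bare_gene_is_none(self):
        _, gene = _tir_genome(with_downstream=False)
        call = classify_gene_flanks(gene, [], [])
        assert call.kind == "none"

    def test_rep_evidence_beats_tirs(self):
        seq, gene = _tir_genome()
        tirs = find_tirs(seq, gene)
        els = [make_el("r1", 430, 452)]
        call = classify_gene_flanks(gene, els, tirs)
        assert call.kind == "REPtron"
        assert call.tir_note


class TestMotifScan:
    def test_direct_match(self):
        hits = scan_motif("GGGGACAC")
        assert (0, "+") in hits

    def test_violating_position_rejected(self):
        assert scan_motif("GGGGTTAC") == []

    def test_minus_strand_reported(self):
        seq = "TTTT" + reverse_complement("GGGGACAC") + "TTTT"
        hits = scan_motif(seq)
        assert hits == [(4, "-")]


class TestTirCensus:
    def _genome(self, seed=9):
        rng = np.random.default_rng(seed)
        bg = list(random_background(rng, 3000, 0.5))
        arm = random_background(rng, 20, 0.5)
        rc = reverse_complement(arm)
        placements = [
            (100, arm), (600, rc),               # 2 isolated singletons
            (1200, arm), (1260, rc),             # inverted pair
            (2000, arm), (2060, rc), (2120, arm)  # a triple
        ]
        for pos, s in placements:
            bg[pos: pos + 20] = list(s)
        return {"c1": "".join(bg)}, arm

    def test_partition_counts(self):
        genome, arm = self._genome()
        counts = tir_family_census(genome, arm, max_mismatch=1)
        assert counts == {"S": 2, "D": 1, "G": 1, "total": 7}

    def test_census_conserved_under_reverse_complement(self):
        genome, arm = self._genome()
        rc_genome = {"c1": reverse_complement(genome["c1"])}
        assert tir_family_census(genome, arm, max_mismatch=1) == \
            tir_family_census(rc_genome, arm, max_mismatch=1)
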