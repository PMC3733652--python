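"""Dimer pairing, composition, clustering and spacer features."""

import random

import pytest

from reptag.detect import RepElement
from reptag.topology import (
    analyze_spacer,
    classify_composition,
    classify_dimers,
    complementary_end_len,
    group_clusters,
    pair_dimers,
    partition_elements,
)


def make_el(eid, start, span=27, strand="+", family="CGTC-1",
            arm5="ATGGCACG", loop="GTTC"):
    from reptag.seqcore import reverse_complement

    return RepElement(
        element_id=eid, contig="c1", start=start, end=start + span,
        strand=strand, family_id=family, tag_seq="CGTC", extra_seq="",
        arm5_seq=arm5, loop_seq=loop,
        arm3_seq=reverse_complement(arm5), tail_seq="CCA",
        stem_mismatches=0, consensus_mismatches=0, wobble_pairs=0,
    )


class TestDimerTyping:
    def test_tags_outward_is_head_head(self):
        # + then -: both tags point away from the spacer
        els = [make_el("a", 100, strand="+"), make_el("b", 157, strand="-")]
        dimers, partner = pair_dimers(els)
        assert len(dimers) == 1
        assert dimers[0].topo == "HH"
        assert dimers[0].spacer_len == 30
        assert partner == {"a": "b", "b": "a"}

    def test_tags_inward_is_tail_tail(self):
        els = [make_el("a", 100, strand="-"), make_el("b", 152, strand="+")]
        dimers, _ = pair_dimers(els)
        assert dimers[0].topo == "TT"
        assert dimers[0].spacer_len == 25

    def test_tandem_is_head_tail(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 137, strand="+")]
        dimers, _ = pair_dimers(els)
        assert dimers[0].topo == "HT"
        assert dimers[0].spacer_len == 10

    def test_wide_gap_leaves_singletons(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 277, strand="+")]
        dimers, partner = pair_dimers(els, max_spacer=100)
        assert dimers == [] and partner == {}

    def test_adjacency_flagged(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 129, strand="-")]
        dimers, _ = pair_dimers(els)
        assert dimers[0].adjacent  # 2 bp spacer

    def test_typing_invariant_under_mirror(self):
        # mirroring swaps order and flips strands; HH stays HH etc.
        for strands, topo in ((("+", "-"), "HH"), (("-", "+"), "TT"),
                              (("+", "+"), "HT")):
            els = [make_el("a", 100, strand=strands[0]),
                   make_el("b", 160, strand=strands[1])]
            L = 400
            flipped = "-+"
            mirrored = [
                make_el("b'", L - els[1].end,
                        strand=flipped[els[1].strand == "-"]),
                make_el("a'", L - els[0].end,
                        strand=flipped[els[0].strand == "-"]),
            ]
            d1, _ = pair_dimers(els)
            d2, _ = pair_dimers(mirrored)
            assert d1[0].topo == d2[0].topo == topo


class TestComposition:
    def test_identical_partners_homodimer(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 157, strand="-")]
        dimers, _ = pair_dimers(els)
        d = classify_dimers(dimers, els)[0]
        assert d.composition == "homodimer"

    def test_different_loops_heterodimer(self):
        els = [
            make_el("a", 100, strand="+", family="GTAG-3", loop="GCAGGC"),
            make_el("b", 160, strand="-", family="GTAG-3",
                    loop="GCCGTATAGGC"),
        ]
        dimers, _ = pair_dimers(els)
        assert classify_dimers(dimers, els)[0].composition == "heterodimer"

    def test_cross_family_hybrid(self):
        els = [
            make_el("a", 100, strand="+", family="GTAG-6"),
            make_el("b", 160, strand="-", family="GTAG-8"),
        ]
        dimers, _ = pair_dimers(els)
        assert classify_dimers(dimers, els)[0].composition == "hybrid"

    def test_unassigned_member_flagged(self):
        from reptag.detect import UNASSIGNED

        els = [make_el("a", 100), make_el("b", 160, family=UNASSIGNED)]
        dimers, _ = pair_dimers(els)
        assert classify_composition(dimers[0],
                                    {e.element_id: e for e in els}) is None


class TestClusters:
    def test_singleton_next_to_dimer_is_trimer(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 167, strand="-"),
               make_el("c", 234, strand="+")]
        part = partition_elements(els)
        assert len(part.clusters) == 1
        assert len(part.clusters[0].members) == 3
        assert part.dimers == []  # absorbed into the cluster
        assert set(part.roles.values()) == {"G"}

    def test_two_elements_stay_a_dimer(self):
        els = [make_el("a", 100, strand="+"), make_el("b", 160, strand="-")]
        part = partition_elements(els)
        assert part.clusters == []
        assert len(part.dimers) == 1

    def test_five_element_tandem_array(self):
        els = [make_el(f"e{i}", 100 + 67 * i, strand="+") for i in range(5)]
        clusters, kept = group_clusters(els, [])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_partition_conservation(self):
        els = (
            [make_el("s1", 100), make_el("s2", 1000)]
            + [make_el("d1", 2000, strand="+"),
               make_el("d2", 2060, strand="-")]
            + [make_el(f"g{i}", 3000 + 67 * i) for i in range(3)]
        )
        part = partition_elements(els)
        lhs, covered = part.conservation_identity()
        assert lhs == covered == len(els)


class TestSpacerFeatures:
    def _dimer_over(self, spacer: str):
        els = [make_el("a", 0, span=10, strand="+"),
               make_el("b", 10 + len(spacer), span=10, strand="-")]
        dimers, _ = pair_dimers(els)
        seq = "GGGGGGGGGG" + spacer + "CCCCCCCCCC"
        return dimers[0], seq

    def test_complementary_ends(self):
        spacer = "GGCCAT" + "TCTCTCTCTCTCTCTCTCTT" + "ATGGCC"
        d, seq = self._dimer_over(spacer)
        feats = analyze_spacer(d, seq)
        assert feats.length == len(spacer)
        assert feats.complementary_end_len == 6

    def test_planted_hairpin_reported(self):
        arm = "GGCGC"
        spacer = "ATTATTAT" + arm + "TTT" + "GCGCC" + "ATTATTAT"
        d, seq = self._dimer_over(spacer)
        feats = analyze_spacer(d, seq, min_arm=4, max_loop=8)
        assert len(feats.embedded_sls) >= 1
        assert max(h.arm_len for h in feats.embedded_sls) >= 4

    def test_zero_length_spacer(self):
        d, seq = self._dimer_over("")
        feats = analyze_spacer(d, seq)
        assert feats.length == 0
        assert feats.complementary_end_len == 0
        assert feats.embedded_sls == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_recomputation(self, seed):
        r = random.Random(seed)
        spacer = "".join(r.choice("ACGT") for _ in range(40))
        d, seq = self._dimer_over(spacer)
        feats = analyze_spacer(d, seq, min_arm=4, max_loop=8)
        # independent recomputation of the complementary-end run
        k = 0
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        while k < 20 and (spacer[k], spacer[39 - k]) in wc:
            k += 1
        assert feats.complementary_end_len == k == \
            complementary_end_len(spacer)
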