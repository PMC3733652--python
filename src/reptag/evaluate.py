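"""Scoring pipeline output against a synthetic-genome truth table.

These helpers turn a :class:`~reptag.pipeline.PipelineResult` and the
generator's truth table into recall/precision and agreement figures for
detection, dimer topology and composition, context categories and the
topology conservation identity. They are used by both the test suite and
the acceptance script.
"""

from __future__ import annotations

import pandas as pd

from .context import classify_gene_flanks, find_tirs, tir_family_census
from .pipeline import PipelineResult
from .synthetic import SyntheticGenome


def _truth_reps(truth: pd.DataFrame) -> pd.DataFrame:
    return truth[truth["kind"] == "rep"].copy()


def detection_scores(result: PipelineResult,
                     truth: pd.DataFrame) -> dict[str, float]:
    """Recall/precision of element calls against planted truth.

    A call matches when coordinates, strand and family all agree.
    """
    reps = _truth_reps(truth)
    truth_keys = {
        (int(r.start), int(r.end), r.strand, r.family_id)
        for r in reps.itertuples()
    }
    det_keys = {
        (el.start, el.end, el.strand, el.family_id)
        for el in result.elements
    }
    tp = len(truth_keys & det_keys)
    recall = tp / len(truth_keys) if truth_keys else 1.0
    precision = tp / len(det_keys) if det_keys else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(truth_keys),
        "n_detected": len(det_keys),
    }


def _expected_dimers(truth: pd.DataFrame):
    """(member coordinate pair, topo, composition) for every planted dimer."""
    reps = _truth_reps(truth)
    reps = reps[reps["role"] == "D"].sort_values("start")
    rows = list(reps.itertuples())
    out = []
    for a, b in zip(rows[::2], rows[1::2]):
        coords = frozenset(
            {(int(a.start), int(a.end)), (int(b.start), int(b.end))}
        )
        out.append((coords, a.architecture, a.composition or ""))
    return out


def topology_scores(result: PipelineResult,
                    truth: pd.DataFrame) -> dict[str, float]:
    """Agreement of dimer topology/composition and cluster membership."""
    by_id = {el.element_id: el for el in result.elements}
    found = {}
    for d in result.partition.dimers:
        a, b = (by_id[m] for m in d.members)
        coords = frozenset({(a.start, a.end), (b.start, b.end)})
        found[coords] = (d.topo, d.composition or "")
    expected = _expected_dimers(truth)
    n_ok = 0
    for coords, topo, comp in expected:
        got = found.get(coords)
        if got is None:
            continue
        if got[0] == topo and (not comp or got[1] == comp):
            n_ok += 1
    dimer_acc = n_ok / len(expected) if expected else 1.0

    reps = _truth_reps(truth)
    grouped = reps[reps["role"] == "G"]
    cluster_members_exp = {
        (int(r.start), int(r.end)) for r in grouped.itertuples()
    }
    cluster_members_found = {
        (by_id[m].start, by_id[m].end)
        for c in result.partition.clusters
        for m in c.members
    }
    cluster_acc = (
        1.0
        if cluster_members_exp == cluster_members_found
        else len(cluster_members_exp & cluster_members_found)
        / max(1, len(cluster_members_exp | cluster_members_found))
    )

    roles_exp = {
        (int(r.start), int(r.end)): r.role for r in reps.itertuples()
    }
    n_role_ok = 0
    for el in result.elements:
        exp = roles_exp.get((el.start, el.end))
        if exp is not None and result.partition.roles[el.element_id] == exp:
            n_role_ok += 1
    role_acc = n_role_ok / len(roles_exp) if roles_exp else 1.0
    return {
        "dimer_accuracy": dimer_acc,
        "cluster_accuracy": cluster_acc,
        "role_accuracy": role_acc,
        "n_dimers_expected": len(expected),
    }


def context_scores(result: PipelineResult,
                   truth: pd.DataFrame) -> dict[str, float]:
    """Agreement of context categories, distances and stop sharing."""
    reps = _truth_reps(truth)
    asserted = reps[reps["context"] != ""]
    ctx_by_coords = {}
    el_by_id = {el.element_id: el for el in result.elements}
    for rec in result.contexts:
        el = el_by_id[rec.element_id]
        ctx_by_coords[(el.start, el.end)] = rec
    n = 0
    n_ok = 0
    for r in asserted.itertuples():
        rec = ctx_by_coords.get((int(r.start), int(r.end)))
        n += 1
        if rec is None:
            continue
        if rec.category != r.context:
            continue
        if r.dist_upstream != "" and not pd.isna(r.dist_upstream):
            if int(float(r.dist_upstream)) != rec.dist_upstream:
                continue
            if int(float(r.dist_downstream)) != rec.dist_downstream:
                continue
        if bool(r.provides_stop) != rec.provides_stop:
            continue
        if r.context == "intragenic" and r.peptide:
            if rec.encoded_peptide != r.peptide:
                continue
        n_ok += 1
    return {
        "context_accuracy": n_ok / n if n else 1.0,
        "n_context_asserted": n,
    }


def conservation_holds(result: PipelineResult) -> bool:
    lhs, covered = result.partition.conservation_identity()
    return lhs == covered == len(result.elements)


def transposase_scores(result: PipelineResult,
                       syn: SyntheticGenome) -> dict[str, float]:
    """REPtron/TIRtron call agreement and TIR-family census agreement."""
    truth = syn.truth
    genes = truth[truth["kind"] == "transposase_gene"]
    gene_orfs = {o.orf_id: o for o in syn.orfs}
    contig = syn.spec.name
    seq = syn.genome[contig]
    n = 0
    n_ok = 0
    census_ok = True
    for r in genes.itertuples():
        gene = gene_orfs[r.feature_id]
        tirs = find_tirs(seq, gene)
        call = classify_gene_flanks(gene, result.elements, tirs)
        n += 1
        if call.kind == r.gene_kind:
            n_ok += 1
        if r.gene_kind == "TIRtron" and call.tir_pairs:
            arm = call.tir_pairs[0].up_seq
            # planted arm copies are exact, so census with a tight
            # substitution tolerance — chance matches are then negligible
            counts = tir_family_census(syn.genome, arm, max_mismatch=1)
            arms = truth[truth["kind"] == "tir_arm"]
            labels = list(arms["architecture"])
            s_exp = sum(1 for x in labels if x in ("up", "down", "S"))
            d_exp = sum(1 for x in labels if x == "D") // 2
            g_rows = [x for x in labels if x.startswith("G") and x not in
                      ("", "S", "D")]
            g_exp = len({x for x in g_rows})  # one group per Gn plant
            census_ok = census_ok and (
                counts["S"] == s_exp
                and counts["D"] == d_exp
                and counts["G"] == g_exp
            )
    return {
        "gene_call_accuracy": n_ok / n if n else 1.0,
        "tir_census_ok": census_ok,
        "n_genes": n,
    }


def mirrored_elements_match(result_fwd: PipelineResult,
                            result_rev: PipelineResult,
                            genome_len: int) -> bool:
    """Is the reverse-complement run the coordinate mirror of the forward run?"""
    def keyset(res, mirror: bool):
        out = set()
        for el in res.elements:
            if mirror:
                out.add(
                    (genome_len - el.end, genome_len - el.start,
                     "-" if el.strand == "+" else "+", el.family_id)
                )
            else:
                out.add((el.start, el.end, el.strand, el.family_id))
        return out

    if keyset(result_fwd, False) != keyset(result_rev, True):
        return False
    topo_fwd = sorted(d.topo for d in result_fwd.partition.dimers)
    topo_rev = sorted(d.topo for d in result_rev.partition.dimers)
    return topo_fwd == topo_rev
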