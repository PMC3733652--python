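"""Census tables and distance profiles.

The family census mirrors the field's standard presentation: per family,
counts of single elements (S), dimers by type (HH/TT/HT) and grouped
elements (G), with hybrid dimers — partners from different families —
counted as singletons of their own families. The conservation identity
S + 2·D + Σ|G| = total elements must hold for every census.
"""

from __future__ import annotations

import pandas as pd

from .topology import TopologyPartition


def summarize(elements, partition: TopologyPartition) -> pd.DataFrame:
    """Per-family S / D(HH,TT,HT) / G census.

    ``G`` counts groups touched by the family; ``grouped_elements`` the
    family's members inside groups (the Σ|G| term of the conservation
    identity). Hybrid dimer components are tallied as singletons.
    """
    by_id = {e.element_id: e for e in elements}
    rows: dict[str, dict] = {}

    def row(fam: str) -> dict:
        return rows.setdefault(
            fam,
            {"family_id": fam, "S": 0, "D_HH": 0, "D_TT": 0, "D_HT": 0,
             "G": 0, "grouped_elements": 0, "total": 0},
        )

    hybrid_members: set[str] = set()
    for d in partition.dimers:
        if d.composition == "hybrid":
            hybrid_members.update(d.members)
            continue
        fam = by_id[d.members[0]].family_id
        r = row(fam)
        r[f"D_{d.topo}"] += 1
        r["total"] += 2
    for el in partition.singletons:
        r = row(el.family_id)
        r["S"] += 1
        r["total"] += 1
    for eid in hybrid_members:
        el = by_id[eid]
        r = row(el.family_id)
        r["S"] += 1
        r["total"] += 1
    for cluster in partition.clusters:
        fams = {}
        for eid in cluster.members:
            el = by_id[eid]
            fams.setdefault(el.family_id, 0)
            fams[el.family_id] += 1
        for fam, n in fams.items():
            r = row(fam)
            r["G"] += 1
            r["grouped_elements"] += n
            r["total"] += n
    out = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["family_id"]),
        columns=["family_id", "S", "D_HH", "D_TT", "D_HT", "G",
                 "grouped_elements", "total"],
    )
    return out


def census_conserved(census: pd.DataFrame) -> bool:
    """S + 2·D + Σ|G| = total, per family and overall."""
    if census.empty:
        return True
    lhs = (
        census["S"]
        + 2 * (census["D_HH"] + census["D_TT"] + census["D_HT"])
        + census["grouped_elements"]
    )
    return bool((lhs == census["total"]).all())


def distance_profile(contexts) -> dict[str, list[int]]:
    """Per-category ascending distance vectors.

    Upstream and downstream distances are kept separate in every
    category (the uni-REP convention, where the two sides play
    different roles, applied uniformly).
    """
    out: dict[str, list[int]] = {}
    for rec in contexts:
        if rec.category not in ("conv", "div", "uni"):
            continue
        for side, dist in (
            ("upstream", rec.dist_upstream),
            ("downstream", rec.dist_downstream),
        ):
            if dist is None:
                continue
            out.setdefault(f"{rec.category}_{side}", []).append(dist)
    return {k: sorted(v) for k, v in sorted(out.items())}
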