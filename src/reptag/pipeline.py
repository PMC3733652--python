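"""End-to-end orchestration: scan, prune, partition, census, context."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import FamilyDefinition, load_catalog
from .context import ContextRecord, OrfRecord, classify_all_contexts
from .detect import (
    DEFAULT_MAX_STEM_MISMATCH,
    DEFAULT_PRUNE_MISMATCH,
    RepElement,
    prune_elements,
    scan_tagged_elements,
    sequence_type_census,
)
from .report import summarize
from .topology import TopologyPartition, pair_dimers, partition_elements


@dataclass
class PipelineResult:
    elements: list[RepElement]
    partition: TopologyPartition
    census: pd.DataFrame
    st_census: pd.DataFrame
    contexts: list[ContextRecord] = field(default_factory=list)


def run_pipeline(
    genome: dict[str, str],
    catalog: list[FamilyDefinition] | None = None,
    orfs: list[OrfRecord] | None = None,
    max_stem_mismatch: int = DEFAULT_MAX_STEM_MISMATCH,
    prune_mismatch: int = DEFAULT_PRUNE_MISMATCH,
    max_spacer: int = 100,
    min_aa: int = 120,
    allow_wobble: bool = True,
) -> PipelineResult:
    """Scan a genome and derive the full repeat annotation.

    Scanning retains elements with up to ``max_stem_mismatch`` unpaired
    stem positions so that weak dimer partners remain discoverable;
    pruning then drops unpartnered elements beyond ``prune_mismatch``
    and loop outliers, and the retained set is partitioned into
    singletons, dimers and clusters, censused, and (when annotations
    are supplied) classified against the ORF landscape.
    """
    if catalog is None:
        catalog = load_catalog()
    raw = scan_tagged_elements(
        genome, catalog,
        max_stem_mismatch=max_stem_mismatch, allow_wobble=allow_wobble,
    )
    _, partner = pair_dimers(raw, max_spacer=max_spacer)
    kept = prune_elements(raw, partner, catalog, max_mismatch=prune_mismatch)
    part = partition_elements(kept, max_spacer=max_spacer,
                              cluster_gap=max_spacer)
    census = summarize(kept, part)
    st = sequence_type_census(kept)
    contexts = (
        classify_all_contexts(kept, orfs, genome, min_aa=min_aa)
        if orfs else []
    )
    return PipelineResult(
        elements=kept, partition=part, census=census, st_census=st,
        contexts=contexts,
    )
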