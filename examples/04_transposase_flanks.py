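"""REPtrons and TIRtrons: transposase genes and their flanking repeats.

Tyrosine-transposase genes associated with repeats come in two
geometries: flanked by REP monomers/dimers (REPtrons) or by long
terminal inverted repeats unrelated to REPs (TIRtrons). This example
classifies the transposase genes of a synthetic genome, scans the
gene for the conserved GGGGWSAS motif, and censuses the TIR arm
family genome-wide with the same S/D/G partition used for REPs.
"""

from reptag import load_catalog, run_pipeline
from reptag.context import (
    classify_gene_flanks,
    find_tirs,
    scan_motif,
    tir_family_census,
)
from reptag.synthetic import default_genome_spec, generate_genome

syn = generate_genome(default_genome_spec(seed=2, length=100_000))
result = run_pipeline(syn.genome, load_catalog())

contig = syn.spec.name
seq = syn.genome[contig]
genes = [o for o in syn.orfs if "transposase" in o.annotation]
for gene in genes:
    tirs = find_tirs(seq, gene)
    call = classify_gene_flanks(gene, result.elements, tirs)
    print(f"{gene.orf_id}: {call.kind}")
    motif_hits = scan_motif(seq[gene.start: gene.end])
    print(f"  GGGGWSAS motif hits inside the gene: {len(motif_hits)}")
    if call.kind == "REPtron":
        print(f"  flanking repeat elements: {len(call.rep_ids)}")
    elif call.kind == "TIRtron":
        best = call.tir_pairs[0]
        print(f"  TIR arms: {best.arm_len} bp, "
              f"{best.mismatches} substitution(s)")
        census = tir_family_census(syn.genome, best.up_seq, max_mismatch=1)
        print(f"  genome-wide TIR family census: S={census['S']} "
              f"D={census['D']} G={census['G']} (total {census['total']})")
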