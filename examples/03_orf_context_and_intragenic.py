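"""Relate repeats to the coding landscape.

Classifies every detected element against the ORF annotations: conv-,
div- and uni- elements lie between convergently, divergently and
unidirectionally transcribed ORFs; elements wholly inside a coding
sequence of at least 120 codons are intragenic and report the amino
acids they encode in frame. Elements whose GTAG tag supplies the TAG
stop codon of the upstream ORF are flagged.
"""

from collections import Counter

from reptag import load_catalog, run_pipeline
from reptag.report import distance_profile
from reptag.synthetic import default_genome_spec, generate_genome

syn = generate_genome(default_genome_spec(seed=5, length=80_000))
result = run_pipeline(syn.genome, load_catalog(), orfs=syn.orfs)

counts = Counter(rec.category for rec in result.contexts)
print("context categories:", dict(counts))

prof = distance_profile(result.contexts)
print("\nconv upstream distances (sorted):", prof.get("conv_upstream"))

for rec in result.contexts:
    if rec.category == "intragenic":
        print(f"\nintragenic element {rec.element_id} in {rec.upstream_orf}"
              f" ({rec.region}): encodes '{rec.encoded_peptide}'")
    if rec.provides_stop:
        print(f"\nelement {rec.element_id} supplies the TAG stop codon of "
              f"ORF {rec.upstream_orf}")
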