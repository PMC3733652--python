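# Default family catalog: 24 GTAG + 4 CGTC tagged-REP families.
#
# One record per family, key: value lines, records separated by blank lines.
# Fields:
#   family           family identifier (required, unique)
#   super_family     GTAG or CGTC
#   tag              canonical 4 bp terminal motif
#   tag_alternatives space-separated degenerate 4-mers also accepted as tags
#   tag_end          five_prime (default) or three_prime: element end carrying
#                    the tag on the element strand
#   extra_bases      unpaired bases between tag and stem (GTAG-1/2 only)
#   arms             space-separated left-arm consensus variants (NC-IUB);
#                    the right arm is the reverse complement
#   arm_source       stated (attested verbatim) or representative (a plausible
#                    stand-in consistent with the attested geometry; full
#                    per-position consensi are published only graphically)
#   loop_range       min-max loop length in bp
#   loop_consensus   degenerate loop consensus (fixed-length loop families)
#   loop_classes     space-separated left/right loop terminal-motif pairs
#   long_loop        true relaxes the super-family loop-length ceiling
#   tail             unpaired 3 bp motif at the untagged end
#   species_variant  <name> key=value overrides (e.g. shorter stems in one
#                    species)
#
# Geometry constraints carried by this catalog (stems 5-13 bp for GTAG with
# most 6-9, 8-9 bp for CGTC; loops 2-20 bp for GTAG, 4-5 bp for CGTC; CGTC
# stems opening with complementary A/T residues; CCA tails on CGTC elements;
# GW extra bases and 3 bp tails on GTAG-1/2; 5 bp Thauera sp. MZ1T GTAG-1
# stems; 12-13 bp GTAG-24 stems; GTGG-tagged GTAG-20 elements; long
# GCGG/CCGC loops in GTAG-14; 9-15 bp loops in GTAG-15) are text-attested.

family: GTAG-1
super_family: GTAG
tag: GTAG
extra_bases: GW
arms: GCCTGGCC
arm_source: representative
loop_range: 2-2
loop_consensus: TY
tail: GGA
species_variant: Thauera_MZ1T arms=GCCTG

family: GTAG-2
super_family: GTAG
tag: GTAG
extra_bases: GW
arms: CGGTTCGA
arm_source: representative
loop_range: 2-2
loop_consensus: TY
tail: TTC

family: GTAG-3
super_family: GTAG
tag: GTAG
tag_alternatives: GYAG
arms: TGCCGGA
arm_source: representative
loop_range: 2-12
loop_classes: GC/GC GGC/GCC GRCG/CGYC

family: GTAG-4
super_family: GTAG
tag: GTAG
arms: GAGCGGTT
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-5
super_family: GTAG
tag: GTAG
arms: CCTGACGT
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-6
super_family: GTAG
tag: GTAG
tag_alternatives: GYRG
arms: CCCTGCTA
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-7
super_family: GTAG
tag: GTAG
arms: GGAGCAAC
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-8
super_family: GTAG
tag: GTAG
arms: TCGCTCCA
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-9
super_family: GTAG
tag: GTAG
arms: CATGGCGA
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-10
super_family: GTAG
tag: GTAG
arms: CGGAACT
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-11
super_family: GTAG
tag: GTAG
arms: GGTCTAC GGACTTC
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-12
super_family: GTAG
tag: GTAG
arms: TACGGGA
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-13
super_family: GTAG
tag: GTAG
arms: AGGCGTTC
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-14
super_family: GTAG
tag: GTAG
tag_alternatives: GTRG
arms: GTTCGGCA
arm_source: representative
loop_range: 4-27
loop_classes: GCGG/CCGC GC/GC
long_loop: true

family: GTAG-15
super_family: GTAG
tag: GTAG
tag_alternatives: GTMG
arms: ATCCGTGG
arm_source: representative
loop_range: 9-15
loop_classes: GC/GC GGC/GCC

family: GTAG-16
super_family: GTAG
tag: GTAG
arms: CAGTTGC
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-17
super_family: GTAG
tag: GTAG
arms: CTGTCCAA
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-18
super_family: GTAG
tag: GTAG
arms: TTGGCGT
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-19
super_family: GTAG
tag: GTAG
arms: GACCTCGT
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-20
super_family: GTAG
tag: GTAG
tag_alternatives: GTGG
arms: ACTGCGA
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-21
super_family: GTAG
tag: GTAG
arms: ATGCGTTG
arm_source: representative
loop_range: 3-3
loop_consensus: CMA

family: GTAG-22
super_family: GTAG
tag: GTAG
arms: CGAGGTCAT
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-23
super_family: GTAG
tag: GTAG
arms: CCGCCAG
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: GTAG-24
super_family: GTAG
tag: GTAG
arms: GGCACGTTCACC GGCACGTTCTACC
arm_source: representative
loop_range: 2-2
loop_consensus: TY

family: CGTC-1
super_family: CGTC
tag: CGTC
tag_alternatives: TGTC CCTC
arms: ATGGCACG
arm_source: representative
loop_range: 4-4
loop_consensus: GTTC
tail: CCA

family: CGTC-2
super_family: CGTC
tag: CGTC
tag_alternatives: TGTC CCTC
arms: ATCCTGGA
arm_source: representative
loop_range: 5-5
loop_consensus: GTTCA
tail: CCA

family: CGTC-3
super_family: CGTC
tag: CGTC
tag_alternatives: TGTC CCTC
arms: ATGAGGCTC
arm_source: representative
loop_range: 5-5
loop_consensus: CTTCG
tail: CCA

family: CGTC-4
super_family: CGTC
tag: CGTC
tag_alternatives: TGTC CCTC
arms: ATCGAAGGC
arm_source: representative
loop_range: 5-5
loop_consensus: GAACA
tail: CCA
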