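# Target palindromes regularly hosting repeats of specific families.
# '••' marks the insertion point of the repeat dimer; '-' is an alignment
# gap; capital letters denote bases that pair between the two halves,
# lowercase letters unpaired or variable residues.
A_variabilis_GTAG-15: TATAGGAnTnnnATTTGATTnnTGAAA••TTTCAnnAATCAAATnnnAnTCCTATA
H_neapolitanus_CGTC-1: GGGaaGCTT-GAAAaACC••attcacgGGTaTTTCgAAGC-gCCC
# Small-palindrome consensus targeted by GTAG-23 insertions: arms of 7 bp
# around a 3-4 bp loop (recorded here as arm (loop-range) arm).
T_roseum_GTAG-23: CCGSSCC (n3,4) GGSSCGG
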