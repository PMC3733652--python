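# Methods

## The element model

A tagged REP is modelled as a fixed-order concatenation of segments on
its own strand:

```
tag(4) · extra(0–2) · arm5(L) · loop(l) · arm3(L) · tail(0–3)
```

The tag is the unpaired terminal 4-mer defining the super-family (GTAG
or CGTC); a family may additionally accept listed degenerate tag
variants (GYAG, GYRG, GTRG, GTMG; TGTC, CCTC; GTGG), which count as
variants, never as mismatches. `arm3` is the reverse complement of
`arm5` up to mutation; `extra` (the GW dinucleotide) and the 3 bp
`tail` (CCA in CGTC elements) occur only in the families that define
them. Stems are 5–13 bp in GTAG families (mostly 6–9) and 8–9 bp in
CGTC families; loops 2–20 bp (up to 27 bp in the flagged long-loop
GTAG-14 class) and 4–5 bp respectively. By convention the tag abuts the
element's 5′ end ("tail" side of a dimer; the stem-loop body is the
"head"); the catalog carries this as a per-family field so that a
family could override it.

Two mismatch notions coexist and are both reported per element:

- **consensus mismatches** — positions of `arm5`/`arm3` violating the
  family's degenerate arm consensus (used for family assignment:
  fewest total mismatches wins, ties go to catalog order);
- **stem mismatches** — arm position pairs that fail to base-pair.
  G:T wobble pairs are counted separately and are never mismatches,
  reflecting that many elements appear to act at the RNA level.

## Scanning and pruning

Scanning is a deterministic consensus search, not BLAST seeding: every
occurrence of a permitted tag 4-mer on either strand seeds candidate
geometries (arm variant × loop length within the family range), and a
candidate survives when its arm consensus holds with ≤ 2 mismatches
(`max_stem_mismatch`, default 2). Overlapping candidates (≥ 50% of the
shorter) are competing explanations of one locus; the winner has the
fewest mismatches, then a plausible loop, then the longer stem, then
the earlier catalog family. The final tie-break uses the candidate's
own segment sequences rather than coordinates, so resolution commutes
with reverse complementation of the genome — with coordinate
tie-breaking, a mutated element whose flank happens to spell a tag on
the opposite strand could resolve differently in the two orientations.

Pruning is a second pass, deliberately separated from scanning:
elements with more than one unpaired stem position are discarded
*unless* they are partnered in a dimer (the partner map is computed on
the unpruned set), and elements whose loops are unusual for their
family — length outside the family range, or composition failing the
family's loop consensus or loop-class termini — are discarded
regardless of partnership. The two-mismatch scan ceiling exists
precisely so that rescuable dimer partners are discoverable before
pruning.

A stem "mismatch" is one non-pairing position pair; bulges are not
modelled — families whose published variants differ by a 1 bp
presence/absence are encoded as alternative fixed-length arm variants
(e.g. the 12 and 13 bp stems of GTAG-24).

## Topology

Elements are partitioned into singletons (S), dimers (D) and grouped
elements (G); the classes are mutually exclusive and exhaustive, so
`S + 2·D + Σ|G| = total` is asserted on every run. Pairing is greedy
left-to-right with an inner gap of 0–100 bp (`max_spacer`; partners
1–5 bp apart are flagged adjacent). Dimer type follows tag placement:
outward tags → HH, inward → TT, tandem → HT. Runs of ≥ 3 elements
within the gap threshold become clusters, which supersede pairing while
recording sub-dimers; one element never belongs to two dimers — tandem
arrays are clusters. Composition compares the partners' body sequences:
identical → homodimer; same family → heterodimer; different families →
hybrid, in which case the census counts the two components as
singletons of their own families. Spacers are characterised by their
longest complementary-end run (strict Watson–Crick, outside-in) and by
embedded stem-loops (perfect arms ≥ 4 bp, loops ≤ 8 bp by default).

## Genomic context

Intergenic elements are classified by the strands of the nearest
flanking ORFs: (+,−) → conv, (−,+) → div, equal → uni, missing flank →
contig_edge. A flank may partially overlap the element (distance 0):
this is required because GTAG elements often supply the TAG stop codon
of the upstream ORF, overlapping its last 4 bp. `provides_stop` is true
only when the ORF's stop codon is TAG and coincides, in genome
coordinates and orientation, with the TAG inside the element's tag.
(TAG is the amber stop codon; it is detected by sequence, whatever it
is called.)

An element is intragenic when it lies wholly inside a CDS whose product
is ≥ 120 amino acids — shorter hypothetical ORFs are treated as
annotation noise, so a repeat inside a 119 aa ORF is excluded and the
same repeat inside a 121 aa ORF is reported. Intragenic elements take
precedence over intergenic categories. The encoded peptide translates
the complete in-frame codons overlapping the element, in ORF
orientation, with the bacterial code (table 11); partial codons at the
element edges are excluded. Position along the ORF is labelled NH2 /
internal / COOH with 10% codon-fraction cutoffs at either end — the
labels are standard but no published cutoff exists, so the fraction is
a configurable parameter.

## Transposase association

Tyrosine-transposase genes are classified by their flanks within a
500 bp window: REP monomers or dimers → REPtron; terminal inverted
repeats with no REP evidence → TIRtron; both → REPtron with the TIRs
noted (degenerate repeats adjoined to unrelated stem-loops form
composite TIRs in some genomes). TIR arms (15–60 bp, ≤ 3 substitutions
between the upstream arm and the reverse complement of the downstream
arm) are found by a per-diagonal maximum-scoring-subarray search with
score +1 per match and −4 per mismatch. The score function is the
significance filter: random sequence essentially never sustains a
positive score across ≥ 15 positions, whereas a plain
"≤ 3 mismatches over ≥ 15 bp" window test fires several times per
500 bp window on noise alone, and greedy window extension absorbs
chance-matching flank bases into the arm. Arms overlapping the gene
ends (up to 30 bp) are reported with 5′ov/3′ov flags. TIR arm families
are censused genome-wide with the same S/D/G partition as REPs. TIR
arms near transposase genes share a motif fitting GGGGWSAS; the motif
scan reports exact degenerate matches on both strands.

## Synthetic genomes

The generator emulates the conditions the analysis assumes: i.i.d.
background at a configurable GC fraction (GC content is a knob because
repeat abundance tracks it in real genomes), with planted cassettes
separated by ≥ 50 bp guards. The default study conditions are 100 kb
genomes with ~55 planted elements across 11 families of both
super-families: 18 singletons between conv/div/uni ORF pairs, 10
dimers covering all three topologies (with forced homodimer,
spontaneous heterodimers, one hybrid, adjacent and distant spacers,
planted complementary ends and an embedded spacer hairpin), clusters of
3/4/5, two in-frame intragenic insertions (single and 60 bp dimer), one
stop-codon-sharing element, one REPtron (dimer upstream, singleton
downstream) and one TIRtron with extra arm copies planted as a
singleton, an inverted pair and a triple. Per-element mutation counts
alternate 0/1; each mutation is applied to an arm position and chosen
to violate both the arm consensus and stem pairing (wobble included),
so it costs exactly one mismatch of each kind. Transposase cassettes
carry 520 bp of internal insulation so that flank classification never
sees a neighbouring cassette's repeats.

Two generator details exist to keep the truth table the *unique*
reading of the emitted sequence. First, a planted element is nearly
palindromic, so if the 4 background bases beyond its tail end happened
to spell a tag on the opposite strand, the locus would acquire a
second, equally scoring parse; the generator rewrites such chance
4-mers (in background or plain spacer only). Second, the bases flanking
planted TIR arms are clamped to non-pairing residues so the inverted
repeat is exactly as long as planted. Real genomes contain no such
guards — which is precisely why truly ambiguous parses there are
reported by deterministic tie-break rather than ground truth.

What passing tests on these genomes shows — and what it does not: the
pipeline recovers planted architecture perfectly under the stated
conditions (substitution-only divergence, ≤ 1 mutation per element,
i.i.d. background, complete and in-frame CDS annotations). Real
genomes add indels and bulged stems, mosaic clusters, misannotated or
overlapping ORFs, and repeat families absent from the catalog; recall
there is bounded by catalog fidelity, and the figures from synthetic
runs do not transfer.

## Numerical and interface choices

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive. The stem-loop finder reports, per loop interval, only the
longest arm within the mismatch budget (maximality), sorted by start,
longer arm, shorter loop; it is verified against exhaustive enumeration
over all (start, arm, loop) triples. Mirror symmetry of raw stem-loop
calls holds for strict pairing only — G:T wobble is not
complement-closed (the mirrored pair is A:C), which is an intrinsic
property of wobble, not an implementation artefact; element scanning
remains strand-symmetric because both strands are scanned. Catalog arm
consensi for families whose full alignments are published only
graphically are representative stand-ins consistent with the attested
geometry, flagged `arm_source: representative` in the packaged file;
the same-length arms of any two families differ at ≥ 2
degeneracy-disjoint positions (asserted by a test), which guarantees
unambiguous family assignment for elements with ≤ 1 mutation. Problem
sizes in the test suite and acceptance script (20 genomes × 100 kb,
200 oracle sequences up to 2 kb) were chosen to exercise every planted
feature class at desk scale.
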