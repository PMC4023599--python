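# bzipkit

Grammar-based analysis of the plant **bZIP transcription-factor family**,
built around the grapevine (*Vitis vinifera*) family of 55 members.

bZIP proteins carry a highly conserved two-part domain: a **basic
region** with the consensus `N-x7-R/K` that binds DNA, followed after a
short hinge by a **leucine zipper** — heptad repeats with Leu (or
another bulky hydrophobic residue: Ile, Val, Phe, Met) at the repeat
position, mediating dimerization. `bzipkit` detects this domain
directly from sequence by its structural grammar, then builds the
family-level analyses on top of the fixed numbering frame it provides
(invariant Asn = −18, invariant Arg/Lys = −10, first zipper repeat =
+1, later repeats +8, +15, …):

- **Domain annotation** (`bzipkit.grammar`): anchor search for
  `N-x7-R/K-x9` followed by ≥3 heptad repeats (interruptions by one or
  two non-repeat units tolerated when a later repeat follows); zipper
  length gradients I–IX for 3–11 repeats; substitution reporting at
  the key DNA-binding positions −18/−10/+1/+8/+15; phosphorylation
  motifs `R/KxxS/T` and `S/TxxD/E`.
- **Gene structure** (`bzipkit.structure`): intron phases
  (phase = cumulative CDS length mod 3), protein↔genome coordinate
  mapping, and classification of the nine intron/exon structural
  patterns *a–i* defined by intron count, subregion (basic / hinge /
  zipper), phase and insertion point within the domain.
- **Genome organization** (`bzipkit.organization`): chromosome
  distribution, tandem-array detection, and family-restricted
  summaries of MCScanX collinearity output (duplicate pairs and
  triplets via connected components).
- **Phylogenetic grouping** (`bzipkit.phylogeny`): gap-free domain
  alignment anchored on the −18/+1 frame, p-distances, a
  Saitou–Nei neighbor-joining implementation, and group assignment
  (A–J or UC) by nearest labeled reference.
- **Expression analysis** (`bzipkit.expression`): Pearson
  co-expression with exact t-transform significance
  (t = r·√((n−2)/(1−r²)), df = n−2) and the thresholds p < 0.01,
  |r| ≥ 0.35, r > 0.9; relative qRT-PCR expression by **2^−ΔΔCt**
  with ΔΔCt = (Ct_target − Ct_reference)_treatment −
  (Ct_target − Ct_reference)_control; ≥2-fold responder calls;
  average-linkage clustering on 1 − PCC.
- **Synthetic data** (`bzipkit.simulate`): seeded generators for every
  input with planted ground truth — proteins obeying the grammar,
  gene models with planted intron positions/phases on either strand,
  expression matrices with calibrated correlated blocks, Ct tables
  with planted folds — plus the packaged 55-member family table.

## Worked example

Planting and recovering the nine structural patterns
(`python examples/intron_patterns.py`):

```
planted a (+): zipper P0 at +4 -> called a [ok]
planted b (-): basic P0 at -14, hinge P0 at -5 -> called b [ok]
planted c (+): basic P2 at -14, zipper P0 at +3 -> called c [ok]
...
planted i (+): no domain introns -> called i [ok]
```

Each line shows the planted introns mapped back from the gene model
onto the domain frame — subregion, splicing phase (P0 between codons,
P1/P2 inside a codon) and frame position — and the pattern letter the
rule table assigns. Pattern *b*, for instance, is two phase-0 introns
in the basic region and hinge; pattern *i* has no intron in the domain.

Genome organization of the packaged family
(`python examples/family_organization.py`):

```
55 genes; 53 mapped, 2 on unplaced scaffolds
chr18 holds 11 genes (20.75% of mapped)
chromosomes without family genes: 9, 10, 11, 16, 17
tandem arrays among collinear duplicates: 0
triplicate genes: VvbZIP07/VvbZIP13/VvbZIP47
triplicate genes: VvbZIP14/VvbZIP22/VvbZIP37
```

The uneven distribution, absence of tandem arrays, and the two
triplicates point to family expansion through segmental/whole-genome
duplication rather than local duplication. The other examples cover
domain annotation, group assignment and the expression analyses.

A thin CLI wraps the same functions:
`bzipkit annotate | patterns | organize | group | atlas | qpcr | simulate`
(see `bzipkit --help`).

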