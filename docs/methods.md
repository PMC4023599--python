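# Methods

## The domain grammar

A bZIP domain is recognized purely structurally. An *anchor* is a
position i with Asn at i and Arg or Lys at i+8 (the `N-x7-R/K`
consensus of the basic region). Nine residues after the basic Arg/Lys,
the leucine zipper begins: heptad repeat positions spaced exactly 7
residues apart, each *canonical* when occupied by one of {L, I, V, F,
M}. The zipper is extended repeat by repeat; a non-canonical repeat
position is tolerated only when a later canonical repeat follows, up
to `max_interruptions` (default 2) per domain — real zippers are
occasionally interrupted by one or two spacer units. Trailing
non-canonical positions are never counted, so the zipper always ends
on a canonical repeat.

Anchors are scored by their number of canonical repeats; an anchor
qualifies with at least `min_heptads` (default 3) and the
highest-scoring anchor wins, ties broken by the leftmost anchor so
annotation is deterministic. `heptad_count` counts canonical repeats
by default; `heptad_counting="all"` also counts tolerated
interruptions (published zipper-length tabulations do not state which
convention they use, so both are available; gradients I–IX map counts
3–11 either way).

Numbering frame: the invariant Asn is −18, the basic Arg/Lys −10, the
first zipper repeat +1; consecutive residues advance the frame by 1
and there is no position 0, so the spacings are −18 → −10 (8 residues)
and −10 → +1 (10 residues). Subregion spans are defined as basic =
[−18, −10], hinge = (−10, +1), zipper = [+1, last repeat].

Key-residue reporting compares frame −18/−10/+1/+8/+15 against N, R,
L, L, L. Lys at −10 is flagged as a substitution with a note (it is a
known basic-region variant in one subfamily); `relaxed_basic=True`
additionally admits any residue at −10 during anchor search — such
anchors are always flagged — to catch rare variants like Ile at −10.

## Intron phases and structural patterns

For an intron after cumulative CDS length c (walking the CDS in
transcription order, so minus-strand genes behave exactly like their
mirror), phase = c mod 3 and the junction codon is residue c // 3.
Protein residue i maps to CDS nucleotides [3i, 3i+3), walked across
exons; all internal coordinates are 0-based half-open, with GFF3's
1-based closed convention converted only at the I/O boundary.

An intron belongs to the domain when its junction codon lies in
[−18, zipper end). Subregion assignment uses the junction codon, so a
phase-0 junction exactly at a subregion boundary belongs to the
*downstream* subregion — a deterministic convention for a boundary
case the pattern definitions do not address.

The pattern classifier is a pure top-down decision table over
(subregion, phase, frame position, flanking residues): no domain
intron → *i*; two phase-0 introns in basic+hinge → *b*; one phase-1
basic intron → *g*; phase-2 basic intron with a phase-0 zipper intron
→ *c*/*d*/*e* by the zipper intron's frame position against
breakpoints (default first/second/third heptad: [+1,+8), [+8,+15),
[+15,∞) — the true positions separating *c*, *d* and *e* are not
published, so the breakpoints are configurable); phase-2 basic intron
without a zipper intron → *f*; one phase-0 zipper intron between Gln
and Ala → *a*, with other flanks → *h*; anything else is unclassified
with a diagnostic. Two lettering schemes are emitted because published
per-gene tables label domain-intron-less genes *h* while the prose
definition reserves *i* for that class and *h* for the single-P0-zipper
class; the schemes differ only in the empty case and neither is
"corrected". The text scheme is the default.

## Genome organization

Chromosome distribution counts genes over a supplied chromosome
universe (default 1–19); genes on `*_random`/`Un` scaffolds count as
unmapped and percentages use the mapped total as denominator. Tandem
detection is distance-based by default — homologous family genes on
the same chromosome within 100 kb (start-to-start), optionally limited
by the number of intervening family genes — because a universally
agreed tandem criterion does not exist; qualifying pairs merge
transitively into maximal arrays. Collinearity summaries only *read*
MCScanX-format output (never recompute chaining): anchors are
restricted to pairs where both genes are family members, blocks count
once if they contain any family anchor, and connected components of
the family homology graph expose duplicate pairs and triplets.

## Domain-anchored alignment and grouping

Because the grammar fixes a numbering frame, family domains align
without a progressive aligner: residues at the same frame position are
placed in the same column, absent positions become gaps. Columns run
from −18 to the zipper end of the longest domain by default (shorter
rows right-padded); `extent="common"` truncates at the shortest
domain instead. p-distances use pairwise deletion; a pair with no
comparable column gets distance 1 with a warning. p-distances are
symmetric with zero diagonal but may violate the triangle inequality;
nothing downstream assumes otherwise.

Neighbor joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch lengths by the standard
formulas, negative lengths clamped to 0 with the excess moved to the
sister branch, ties broken by the lexicographically smallest id pair.
On additive matrices the generating topology is recovered exactly and
patristic distances match the input to 1e-9 (tested against an
independent NJ implementation). Group assignment gives each query the
label of its nearest labeled reference by tree path length (raw
distance as fallback); when the two nearest references disagree within
`tie_margin` (default 0.02 substitutions/site — small, explicit,
configurable) the query is labeled UC. Bootstrap (column resampling)
is available but off by default and never feeds group assignment.
Minimum-evolution and parsimony trees are out of scope; nearest-
reference assignment operationalizes what is otherwise a visual clade
reading, and borderline genes may differ from a by-eye grouping.

## Expression analyses

Pearson correlations are classified with two-tailed p-values from the
exact t-transform (df = n−2), no multiple-testing correction:
significant-positive ⟺ p < 0.01 and r ≥ 0.35 (boundary inclusive),
significant-negative ⟺ p < 0.01 and r ≤ −0.35, strong-positive when
additionally r > 0.9. With 54 samples the critical |r| at p = 0.01 is
≈0.35, which is why those two thresholds travel together. Atlas values
are assumed log2-scaled; a flag applies the transform for linear
input. Zero-variance genes are excluded with a warning.

2^−ΔΔCt: technical replicates are averaged at the Ct level within
each biological replicate; each treatment replicate is paired with the
control ΔCt of the same biological replicate (mean control ΔCt as
fallback); biological replicates are averaged at the fold level. The
source protocols do not state this aggregation order; averaging Cts
within and folds across replicates is the conventional choice. Folds
are invariant to any additive shift applied equally to a condition's
target and reference Cts, and the control condition is exactly 1.
Responder calls are inclusive at the threshold ("at least two fold"):
up when any non-control fold ≥ 2, down when any ≤ 1/2, both possible.
Expression clustering is agglomerative with average linkage on
1 − PCC, cut at k = 4 by default (the cluster count reported for
stress-response heatmaps); constant rows fall back to nearest-centroid
assignment with a warning.

## Synthetic data: what it emulates and what it does not

The generators produce inputs whose truth predicts every pipeline
output deterministically at zero noise, and they are bit-reproducible
given (config, seed).

Proteins: filler inside the domain frame is drawn from residues that
can neither seed an anchor (N, R, K) nor read as a repeat (L, I, V, F,
M), so the planted anchor is unique by construction. Flanks are
uniform over all twenty residues, with two safeguards: the
`max_interruptions`+1 heptad-spaced positions immediately after the
planted zipper are forced to filler (otherwise a random hydrophobic
residue would legitimately extend the zipper and the planted repeat
count would be unrecoverable), and a bounded, seeded rejection loop
re-draws flanks in the rare case they contain a competing anchor.

Genes: the CDS is reverse-translated with a fixed codon per amino
acid; each planted intron is realized by cutting the CDS at
3·codon + phase and splicing in a random `GT…AG` intron (76–196 nt);
flanking genomic sequence is 50–150 nt; the minus strand emits a
reverse-complemented contig with mirrored coordinates.

Expression matrices: block members share a latent per-sample profile
mixed as √r·z + √(1−r)·ε, so the population within-block PCC equals
`r_target` exactly; optional extra measurement noise attenuates it to
r/(1+σ²). Defaults mirror a 54-sample atlas. Ct tables: the reference
Ct is constant per condition and the target Ct sits a per-gene ΔCt
baseline above it, shifted by −log2(fold), plus optional cycle noise.

None of the generators emulate microarray probe effects, primer
efficiencies below 100%, alternative splicing, sequencing error, or
genome-scale background sequence — passing round-trip tests
demonstrates internal correctness of the method's logic, not
robustness to those real-data artifacts. Likewise the packaged family
table is a printed summary, not re-derived from genome annotation.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen as the smallest that make each statistical check meaningful:
500 proteins for grammar recovery, all 9 patterns × 2 strands for the
pattern round trip, 50 random additive matrices (4–8 taxa) for NJ,
1000 background pairs at n = 54 for type-I calibration (binomial
standard error ≈0.3 percentage points at the 1% level), 100 seeds for
within-block correlation calibration (tolerance ±0.03 from the
Fisher-z standard error at n = 54). Floating-point tolerances: 1e-12
for correlation oracle agreement, 1e-9 for fold recovery and NJ branch
lengths, exact equality for integer counts and labels.

## Known limitations

- Domain detection is grammar-based; it will miss genuine bZIP domains
  that violate the `N-x7-R/K` spacing and may be stricter than a
  profile-HMM search. Profile search, external-domain motif discovery
  and dimerization-specificity prediction are out of scope.
- The c/d/e breakpoints and the tandem criterion are explicit
  assumptions (configurable), not published values.
- Group assignment by nearest reference requires at least one labeled
  reference per group and does not estimate clade support unless
  bootstrap is explicitly enabled.
- The collinearity module summarizes an existing MCScanX run; block
  counts therefore depend entirely on that upstream run.
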