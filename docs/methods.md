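# Methods

This note records the models, conventions and design choices behind
`mitocomp`, in the spirit of a methods appendix: what each stage computes,
what the defaults mean, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates, annotation model and validation

All coordinates are 1-based and fully inclusive, the convention of published
mitogenome annotation tables. A feature on a circular genome may wrap the
origin (`end < start`); wrapping is rejected on linear genomes. L-strand
features keep H-strand coordinates and carry `strand=L`; sequence extraction
reverse-complements them, so every downstream stage sees transcription-sense
sequence. Legacy tables that mark L-strand rows with a `[C]` token in the
name field are accepted on input.

The validator treats findings as data, not exceptions, with three
severities. ERRORs: coordinates out of range, declared length differing from
the coordinate span, gene start codons outside {ATG, GTG}, stop signals
outside {TAA, TAG, AGA, AGG, TA, T}, and published composition percentages
differing from recomputed ones by more than 0.1 percentage points (the
resolution of 1-decimal printing). Feature overlaps are INFO, because gene
overlaps (atp8/atp6, nad4L/nad4, gene–tRNA junctions) are genuine biology.
Duplicate coordinate spans are WARN: the shipped *X. laevis* table
reproduces its published source verbatim, including a tRNA-Tyr row that
duplicates the tRNA-Ser(UCN) span (6817–6887) while cox1 occupies 5262–6816
— almost certainly a typesetting error, preserved deliberately and flagged.

Gene-order comparison uses the table's row order, not coordinate-sorted
order, precisely so that such coordinate typos cannot defeat an order
comparison; the row order of a curated table is itself the asserted order.
Names are compared case-insensitively and Leu/Ser anticodon labels
(trnL-UUR vs trnL-CUN, trnS-UCN vs trnS-AGY) must match exactly.

Coverage summaries implement the plain formulas: percent reads mapped,
percent nucleotides mapped (each to 2 dp), and mean depth of coverage =
mapped nucleotides / genome length, rounded to an integer. Two cells of the
shipped run table are not reproducible from its own counts: the *X.
victorianus* mean DOC prints as ~186 where 3432828/17716 gives ~194, and its
percent-nucleotides-mapped prints 40.40 where the division gives 40.38. The
formulas are implemented as stated and the discrepancies are documented, not
reconciled.

## Composition, skews, codon usage, translation

Composition counts run over unambiguous bases only; IUPAC ambiguity codes
are excluded from numerators and denominators, and codons containing them
are skipped (tallied separately) in codon-usage counts. Skews are
(A−T)/(A+T) and (G−C)/(G+C); a zero denominator yields an undefined flag
rather than a value. Skews negate exactly under reverse complementation —
an identity the tests assert without tolerance.

Species-level "H-strand protein-coding" summaries exclude the single
L-strand gene (nad6) by default, matching the usual phrasing of such
summaries; a flag includes it, read in its own sense. Because published
species tables rarely state whether they pool genes (length-weighted) or
average per-gene values, both conventions are computed and labelled; the
pooled value is the package's default.

Translation uses the vertebrate mitochondrial code (NCBI table 2: TGA→Trp,
ATA→Met, AGA/AGG→stop), implemented as its own table and cross-checked
against Biopython's on all 64 codons in the tests. CDS lengths that are not
codon multiples are interpreted through the incomplete-stop convention: a
trailing T or TA is completed to TAA by polyadenylation of the transcript,
so `codon_usage` classifies terminal fragments as complete, incomplete or
invalid rather than treating remainder as error.

## Sliding-window divergence

Distances use pairwise deletion: any column with a gap or ambiguity code in
either sequence of a pair is excluded. K(JC) = −(3/4)ln(1 − (4/3)p);
p ≥ 0.75 is past the model's saturation point and yields an undefined value
(NaN), never an exception. Windows advance on alignment coordinates
(midpoints 1-based), matching how sliding-window tools report profiles; a
window is undefined when any contributing pair has fewer than
`min_valid_sites` comparable sites (default window/2 — a guard against
gap-dominated windows), when a pair is saturated, or when the window
touches a masked interval (masks exist because control regions often cannot
be aligned unambiguously). Multi-taxon profiles are the unweighted mean of
K over all unordered pairs. Region capture averages defined window values
whose midpoints fall inside labelled intervals and ranks regions by mean K
— the operation behind "which barcode captures more diversity".

The origin-similarity scan is a brute-force ungapped scan of a motif at
every offset (wrapping the origin on circular genomes), optionally on both
strands, reporting percent identity; it is intended for locating putative
replication-origin sequences (O_H/O_L) in related genomes.

## dN/dS estimation

NG86: each codon position contributes the fraction of its non-stop
single-nucleotide changes that are synonymous (changes creating stops are
excluded from numerator and denominator, so site counts still sum to 3 per
codon); per-pair sites are the average over the two sequences. Codon pairs
differing at k positions are averaged over the k! substitution orderings
that avoid stop intermediates, all equally weighted. For the rare pairs
whose every direct ordering crosses a stop (e.g. AAA↔TGA under this code,
where both two-step intermediates are stops), the steps of the shortest
stop-free detour are classified and the per-step synonymous fraction is
rescaled to the observed number of differences — so pathway-averaged
Sd + Nd always equals the observed nucleotide differences, a property the
tests check exhaustively over all sense-codon pairs. pS = Sd/S and pN =
Nd/N receive the Jukes–Cantor correction; pS or pN ≥ 0.75 sets a
saturation flag. dS = 0 yields ω undefined rather than infinite.

MYN (modified Yang–Nielsen style): the same counting skeleton with three
substitutions. (i) Site classification weights each candidate change by its
TN93 mutation factor — κ_R for purine transitions, κ_Y for pyrimidine
transitions, 1 for transversions, times the target-base frequency (the
codon-frequency-bias factor). (ii) Pathways are weighted by the product of
their step factors. (iii) The multiple-hit correction inverts the expected
p-distance curve of the fitted TN93 rate matrix numerically (Brent's
method, tolerance 1e-12) instead of assuming JC. The TN93 parameters come
from moment inversion of the observed purine-transition, pyrimidine-
transition and transversion proportions pooled over pairs; when the log
arguments are non-positive (saturation, no transversions) the ratios fall
back to 1 with a warning, and negative ratio estimates clamp to a 1e-3
floor. With κ_R = κ_Y = 1 and uniform frequencies all weights are equal and
the TN93 matrix is exactly JC, so MYN reproduces NG86 to numerical
precision; this collapse identity is asserted at 1e-6 (observed ~1e-13) and
is the variant's correctness anchor, since the original tool's exact
algorithm is not published in equation form. Numeric equality with any
particular external implementation is not claimed.

Selection categories use a neutral band of half-width 0.05 around ω = 1
(negative below, positive above, neutral within); undefined ω is
"undetermined".

## Phylogenetics

Gene alignment is a deterministic surrogate for manual in-frame alignment:
CDSs (incomplete stops A-completed, terminal stops stripped) are translated
and pairwise-aligned to the first taxon's protein under BLOSUM62 with a
linear gap penalty of −6 per residue, merged star-wise on reference
coordinates, and back-translated so gaps occupy whole codons. On indel-free
input the alignment is the identity. Supermatrices concatenate genes in
canonical vertebrate order (nad1, nad2, cox1, cox2, atp8, atp6, cox3, nad3,
nad4L, nad4, nad5, nad6, cytb) with partition bounds; an identical site is
a gap-free single-state column. Distances are amino-acid p-distances under
pairwise deletion, optionally Poisson-corrected (−ln(1−p)).

Tree building is canonical neighbor-joining with ties in the Q criterion
broken by the lexicographically smallest pair of subtree labels and
negative branch lengths clamped to zero with a warning; trees are unrooted
unless an outgroup is supplied. NJ on distances deliberately replaces
Bayesian inference here: it is deterministic, dependency-light and
desk-scale, and the claim it supports is topology identity (Robinson–Foulds
distance 0), not branch support. Against full Bayesian analysis of real
data, published supermatrix figures (e.g. total aligned length or percent
identical sites of a by-eye alignment) can only be approximated by the
surrogate aligner, and gap counts may differ.

## The simulator: what it emulates, and what it does not

`generate_annotated_genome` lays out a circular ~17.4 kb genome in
canonical vertebrate order — 13 protein-coding genes, 22 tRNAs, 2 rRNAs,
one control region, with nad6 plus tRNAs Gln, Ala, Asn, Cys, Tyr, Ser(UCN),
Glu and Pro on the L-strand. Gene lengths follow typical frog values, so
the incomplete-stop genes (cox2, cox3, nad3, nad4) arise naturally from
lengths that are not codon multiples. Compositional defaults are the
measured frog regime: GC content 39.3%, H-strand coding GC skew −0.32, AT
skew −0.02, control region 60% AT. Because rejecting stop codons during
ORF sampling depletes A and T, the sampling frequencies are pre-calibrated
by a fixed-point iteration so that the post-rejection expectation matches
the targets; realized pooled skews land within ±0.03 of target at this
genome size. Generated tables always validate cleanly — the generator and
validator are mutual tests.

Evolution is site-wise Markov simulation under TN93 (JC as the equal-rates
case) along a user-supplied Newick tree, indel-free by default so tips
double as an alignment; per-gene rate multipliers scale branch lengths
inside gene intervals. Codon mode is M0-style: single-nucleotide codon
moves, rate proportional to the TN93 nucleotide factor times ω for
nonsynonymous changes, stop codons forbidden, branch lengths in expected
substitutions per codon (dN/dS is invariant to that time scaling). ω = 0 is
allowed and mechanically forces all differences to be synonymous.
`evolve_annotated_genome` combines both modes to evolve a whole annotated
genome into tips that remain valid (start codons and stop signals held
fixed, genes stop-free), which is what the end-to-end pipeline test runs
on. All randomness flows from one recorded integer seed (per-feature
streams are derived deterministically); identical seeds give byte-identical
outputs.

What the simulator does not emulate: indels (off by default; alignment
tests construct them explicitly), tRNA secondary structure, recombination,
heteroplasmy, rate variation within genes, or selection heterogeneity along
a gene. Passing calibration tests therefore shows the estimators are
correct under their own model assumptions at realistic sizes — not that
real mitogenomes satisfy those assumptions.

## Problem sizes and numerical choices

Calibration checks use sizes at which sampling error is small but runs stay
interactive: JC calibration uses 100 replicates of 10 kb pairs at true
distances 0.01–0.3 (mean within 3 standard errors); ω recovery uses 5,000
codons at ω = 0.2 (±0.1) and ω = 1.0 (±0.15); six-taxon topology recovery
uses 100 replicates of 3,780-codon supermatrices — the scale of a real
13-gene mitochondrial supermatrix — on a tree whose shortest internal
branches are 0.02–0.05 substitutions per site, recovering the generating
topology in ≥95% of replicates (observed: 100%). The TN93 moment inversion
warns below 100 comparable sites. Brent inversion of expected p-distance
uses xtol 1e-12; base-frequency estimates carry a 0.5 pseudocount to stay
strictly positive.

## Known limitations

- The MYN variant is this package's pinned, documented interpretation of a
  TN93-weighted counting estimator; other implementations may differ in
  detail, and only the documented properties (collapse identity,
  calibration, bookkeeping) are claimed.
- The star-merge aligner is adequate for closely related, mostly indel-free
  mitochondrial CDSs; it is not a general MSA tool and can be suboptimal
  for many-indel or deeply divergent inputs.
- NJ gives no support values; the toolkit reports topology and branch
  lengths only.
- Annotation validation checks internal consistency and genetic-code
  conventions; it does not re-annotate (no tRNA structure prediction, no
  ORF discovery).
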