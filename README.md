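# mitocomp

A comparative mitogenomics toolkit for vertebrate (especially amphibian)
mitochondrial genomes: annotation modelling and validation, base composition
and strand-skew indices, codon usage under the vertebrate mitochondrial
genetic code, sliding-window nucleotide divergence with Jukes–Cantor
correction, pairwise dN/dS with selection classification, concatenation and
distance-based phylogenetics, sequencing-coverage summaries, and a synthetic
mitogenome-evolution simulator so every stage can be exercised and calibrated
without any downloads.

It is aimed at people characterising newly sequenced mitogenomes — checking
an annotation table against its sequence, quantifying strand asymmetry,
finding variable regions for marker/barcode design, and asking which genes
are under the strongest purifying selection.

## The statistics at the core

**Strand skew.** mtDNA replication leaves the heavy (H) strand single-stranded
longer, producing compositional asymmetry measured as

    AT skew = (A − T) / (A + T)        GC skew = (G − C) / (G + C)

on the reported strand. Frog H-strand protein-coding genes typically show a
strongly negative GC skew (around −0.32: G prefers the L-strand) and a mildly
negative AT skew.

**Sliding-window divergence.** Over an alignment, windows (default 300 bp,
step 10 bp) report K(JC), the Jukes–Cantor-corrected substitutions per site:

    K = −(3/4) · ln(1 − (4/3)·p)

with `p` the mismatch proportion under pairwise deletion. Profiles expose
variable regions (control region, *nad4L*) and conserved ones (*cox1–3*,
*rrnS*), and rank candidate barcode intervals by captured diversity.

**dN/dS.** Pairwise ω = dN/dS is estimated per gene by Nei–Gojobori (NG86)
counting — synonymous/nonsynonymous sites averaged over codon positions,
multi-step codon differences averaged over stop-free substitution pathways —
and by a modified Yang–Nielsen-style variant (MYN) whose site and pathway
weights and multiple-hit correction come from a Tamura–Nei (TN93) model
fitted to the data. With both transition/transversion ratios at 1 and uniform
base frequencies, MYN collapses to NG86 exactly; that identity anchors the
implementation. ω < 1 indicates purifying, ω > 1 positive, ω ≈ 1 neutral
evolution.

**Phylogeny.** Per-gene CDS sets are aligned at the amino-acid level
(BLOSUM62, linear gap penalty), back-translated, concatenated in canonical
vertebrate gene order, and summarised as pairwise Poisson-corrected
amino-acid distances (d = −ln(1 − p)) from which a neighbor-joining tree is
built with deterministic tie-breaking. Topologies are compared by
Robinson–Foulds distance.

## Worked example

```python
import mitocomp as mc
from mitocomp import simulate as sim

# published annotation fixtures ship with the package
table = mc.load_published_feature_table("XB")
print("XB genome length from annotation:", mc.genome_length_from_table(table), "nt")

stats = mc.load_published_read_stats()["XB"]
cov = mc.coverage_summary(stats)
print(f"XB coverage: {cov['pct_reads_mapped']}% reads mapped, "
      f"{cov['pct_nt_mapped']}% nt mapped, mean DOC {cov['mean_doc']}x")

# a synthetic annotated mitogenome with realistic strand asymmetry
genome, synth_table = sim.generate_annotated_genome(sim.default_layout(seed=1))
sk = mc.hstrand_coding_skews(genome, synth_table, method="pooled")
print(f"synthetic genome: {genome.length} nt, "
      f"H-strand coding GC skew {sk['GC_skew']:.3f}, AT skew {sk['AT_skew']:.3f}")

# codon evolution at a known omega, then estimate it back
truth = sim.SimTruth(tree_newick="(A:0.15,B:0.15);", omega={"cox1": 0.2}, seed=1)
tips = sim.evolve_codons(None, truth, gene="cox1", n_codons=5000)["tips"]
from mitocomp.selection import CodonAlignment, ng86_pairwise
r = ng86_pairwise(CodonAlignment(tips, gene="cox1"), ("A", "B"))
print(f"cox1 A-B: dN={r.dN:.4f} dS={r.dS:.4f} omega={r.omega:.3f} ({r.category})")
```

prints

```
XB genome length from annotation: 17474 nt
XB coverage: 97.95% reads mapped, 99.75% nt mapped, mean DOC 9823x
synthetic genome: 17426 nt, H-strand coding GC skew -0.314, AT skew -0.019
cox1 A-B: dN=0.0505 dS=0.2459 omega=0.205 (negative)
```

The first two lines are arithmetic on the shipped annotation and
sequencing-run tables of *Xenopus borealis* (genome length from the last
feature's end coordinate; mapping percentages and mean depth of coverage
from read counts). The third shows the simulator hitting its compositional
targets. The last line recovers the simulated selective regime: a gene
evolved at ω = 0.2 is estimated at 0.205 and classified as under purifying
(negative) selection.

A `mitocomp` console script exposes the same stages
(`validate`, `composition`, `slide`, `kaks`, `phylo`, `coverage`,
`simulate`, `report`); see `mitocomp --help`.

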