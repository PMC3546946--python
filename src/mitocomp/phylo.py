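"""Protein-guided alignment, supermatrix statistics and NJ tree building.

The pipeline mirrors a standard mitogenome phylogeny workflow: per-gene CDS
sets are aligned at the amino-acid level and back-translated to codons,
gene alignments are concatenated into a supermatrix in canonical vertebrate
gene order, amino-acid distances (p or Poisson-corrected, d = -ln(1 - p))
are computed under pairwise deletion, and a neighbor-joining tree is built
with deterministic tie-breaking.  NJ on distances is used as a
deterministic, desk-scale stand-in for full Bayesian inference: the claim
it supports is topology identity, not branch support.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .composition import translate_mito
from .model import PROTEIN_CODING_GENES
from .selection import CodonAlignment

__all__ = [
    "Supermatrix",
    "align_gene_codon_aware",
    "concatenate_and_stats",
    "aa_distance_matrix",
    "nj_tree",
    "compare_topologies",
    "root_at_outgroup",
]

#: canonical concatenation order for the 13 protein-coding genes
GENE_ORDER = ("nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
              "nad3", "nad4L", "nad4", "nad5", "nad6", "cytb")

# Aligner defaults: BLOSUM62 with a linear gap penalty of -6 per residue.
_GAP_SCORE = -6.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = _GAP_SCORE
    aligner.extend_gap_score = _GAP_SCORE
    aligner.mode = "global"
    return aligner


def _prepare_cds(seq: str) -> str:
    """Complete an incomplete terminal stop by A-padding, strip the stop."""
    from .composition import MITO_STOP_CODONS
    seq = seq.upper()
    rem = len(seq) % 3
    if rem:
        seq += "A" * (3 - rem)
    if seq[-3:] in MITO_STOP_CODONS:
        seq = seq[:-3]
    return seq


def _pairwise_to_reference(aligner, ref_aa: str, seq_aa: str):
    """Insertions/matches of ``seq_aa`` relative to reference positions."""
    aln = aligner.align(ref_aa, seq_aa)[0]
    ref_row, seq_row = str(aln[0]), str(aln[1])
    n_ref = len(ref_aa)
    ins: list[str] = ["" for _ in range(n_ref + 1)]
    match: list[str] = ["-"] * n_ref
    ri = 0
    for rc, sc in zip(ref_row, seq_row):
        if rc == "-":
            ins[ri] += sc
        else:
            match[ri] = sc
            ri += 1
    return ins, match


def align_gene_codon_aware(cds_set: dict[str, str], gene: str = "") -> CodonAlignment:
    """Amino-acid-guided multiple alignment of one gene's CDS set.

    Each CDS (incomplete stops A-completed, terminal stop stripped) is
    translated and aligned pairwise to the first taxon's protein with a
    fixed scoring scheme (BLOSUM62, linear gap -6); the pairwise alignments
    are merged on reference coordinates and back-translated to codons.
    Deterministic for fixed inputs.
    """
    if len(cds_set) < 2:
        raise ValueError("need at least two sequences to align")
    labels = list(cds_set)
    prepared = {lab: _prepare_cds(s) for lab, s in cds_set.items()}
    proteins = {lab: translate_mito(s) for lab, s in prepared.items()}

    ref_label = labels[0]
    ref_aa = proteins[ref_label]
    n_ref = len(ref_aa)
    aligner = _make_aligner()

    per_seq = {}
    for lab in labels[1:]:
        per_seq[lab] = _pairwise_to_reference(aligner, ref_aa, proteins[lab])

    max_ins = [0] * (n_ref + 1)
    for ins, _ in per_seq.values():
        for i, chunk in enumerate(ins):
            max_ins[i] = max(max_ins[i], len(chunk))

    aa_rows: dict[str, str] = {}
    ref_cols = []
    for i in range(n_ref):
        ref_cols.append("-" * max_ins[i] + ref_aa[i])
    ref_cols.append("-" * max_ins[n_ref])
    aa_rows[ref_label] = "".join(ref_cols)
    for lab in labels[1:]:
        ins, match = per_seq[lab]
        cols = []
        for i in range(n_ref):
            cols.append(ins[i].ljust(max_ins[i], "-") + match[i])
        cols.append(ins[n_ref].ljust(max_ins[n_ref], "-"))
        aa_rows[lab] = "".join(cols)

    codon_rows = {}
    for lab in labels:
        cds = prepared[lab]
        out = []
        ci = 0
        for aa in aa_rows[lab]:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * ci:3 * ci + 3])
                ci += 1
        if ci != len(cds) // 3:
            raise RuntimeError(f"back-translation misalignment for {lab!r}")
        codon_rows[lab] = "".join(out)
    return CodonAlignment(codon_rows, gene=gene)


@dataclass
class Supermatrix:
    """Concatenated per-gene amino-acid alignments with partition bounds."""

    taxa: list[str]
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]    # (gene, start, end) 1-based

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.sequences[t]}\n")

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tstart\tend\n")
            for g, s, e in self.partitions:
                fh.write(f"{g}\t{s}\t{e}\n")


def concatenate_and_stats(alignments: dict[str, dict[str, str]]) -> dict:
    """Concatenate per-gene amino-acid alignments; report identity stats.

    Genes are concatenated in canonical mitochondrial order (unknown genes
    appended alphabetically).  An identical site is a column with a single
    residue state and no gap.  Returns the supermatrix plus ``n_sites``,
    ``n_identical``, ``pct_identical`` and ``n_gaps``.
    """
    if not alignments:
        raise ValueError("no gene alignments supplied")
    taxa = sorted(next(iter(alignments.values())))
    for gene, aln in alignments.items():
        if sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValueError(f"gene {gene!r}: taxon set mismatch ({missing})")

    known = [g for g in GENE_ORDER if g in alignments]
    extra = sorted(g for g in alignments if g not in GENE_ORDER)
    order = known + extra

    parts = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for gene in order:
        aln = alignments[gene]
        glen = len(next(iter(aln.values())))
        if any(len(s) != glen for s in aln.values()):
            raise ValueError(f"gene {gene!r}: unequal aligned lengths")
        for t in taxa:
            parts[t].append(aln[t].upper())
        partitions.append((gene, pos, pos + glen - 1))
        pos += glen

    seqs = {t: "".join(parts[t]) for t in taxa}
    matrix = Supermatrix(taxa=taxa, sequences=seqs, partitions=partitions)

    n_sites = matrix.n_sites
    n_identical = 0
    n_gaps = 0
    cols = list(zip(*(seqs[t] for t in taxa)))
    for col in cols:
        n_gaps += col.count("-")
        if "-" not in col and len(set(col)) == 1:
            n_identical += 1
    return {
        "supermatrix": matrix,
        "n_sites": n_sites,
        "n_identical": n_identical,
        "pct_identical": 100.0 * n_identical / n_sites,
        "n_gaps": n_gaps,
    }


def aa_distance_matrix(matrix: Supermatrix, correction: str = "none"):
    """Pairwise amino-acid distances under pairwise deletion.

    ``correction="poisson"`` applies d = -ln(1 - p); p = 1 yields ``nan``.
    Returns ``(labels, ndarray)``.
    """
    taxa = matrix.taxa
    if len(taxa) < 3:
        raise ValueError("need at least three taxa for a distance matrix")
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.sequences[taxa[i]], matrix.sequences[taxa[j]]
            valid = mism = 0
            for x, y in zip(a, b):
                if x in "-X" or y in "-X":
                    continue
                valid += 1
                if x != y:
                    mism += 1
            if valid == 0:
                raise ValueError(f"no comparable sites between {taxa[i]} and {taxa[j]}")
            p = mism / valid
            if correction == "poisson":
                d = math.nan if p >= 1.0 else -math.log1p(-p)
            elif correction == "none":
                d = p
            else:
                raise ValueError("correction must be 'none' or 'poisson'")
            D[i, j] = D[j, i] = d
    return taxa, D


def nj_tree(labels: list[str], D: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of subtree labels; negative branch lengths are clamped to zero
    with a warning.  The returned tree is unrooted.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least three taxa")

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0")
            return 0.0
        return x

    nodes = [f"{lab}" for lab in labels]          # newick fragments
    keys = list(labels)                           # min leaf label per node
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}
    active = list(range(n))
    next_id = n

    def d(i, j):
        return dist[(i, j) if i < j else (j, i)]

    frag = {i: nodes[i] for i in active}
    key = {i: keys[i] for i in active}

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                tie = tuple(sorted((key[a], key[b])))
                cand = (q, tie, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = clamp(0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (m - 2)))
        lb = clamp(d(a, b) - la)
        u = next_id
        next_id += 1
        frag[u] = f"({frag[a]}:{la:.10g},{frag[b]}:{lb:.10g})"
        key[u] = min(key[a], key[b])
        for k in active:
            if k in (a, b):
                continue
            duk = clamp(0.5 * (d(a, k) + d(b, k) - d(a, b)))
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (a, b)] + [u]

    a, b = active
    half = clamp(0.5 * d(a, b))
    newick = f"({frag[a]}:{half:.10g},{frag[b]}:{half:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def compare_topologies(a: dendropy.Tree | str, b: dendropy.Tree | str) -> dict:
    """Unrooted Robinson-Foulds distance between two trees.

    Accepts dendropy trees or newick strings; leaf sets must match.
    Returns ``{"rf_distance": int, "identical": bool}``.
    """
    tns = dendropy.TaxonNamespace()

    def load(t):
        s = t if isinstance(t, str) else t.as_string(schema="newick")
        tree = dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)
        tree.is_rooted = False
        tree.encode_bipartitions()
        return tree

    ta = load(a)
    tb = load(b)
    leaves_a = {lf.taxon.label for lf in ta.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError(f"leaf sets differ: {leaves_a ^ leaves_b}")
    rf = dendropy.calculate.treecompare.symmetric_difference(ta, tb)
    return {"rf_distance": int(rf), "identical": rf == 0}


def root_at_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Reroot a copy of the tree on the edge leading to the outgroup clade."""
    t = tree.clone(depth=1)
    t.is_rooted = True      # rooting below makes this explicit
    taxa = [t.taxon_namespace.get_taxon(lab) for lab in outgroup]
    if any(x is None for x in taxa):
        raise ValueError("outgroup taxa not all present in tree")
    mrca = t.mrca(taxa=taxa)
    if mrca is t.seed_node:
        t.reroot_at_edge(t.find_node_with_taxon_label(outgroup[0]).edge,
                         update_bipartitions=True)
    else:
        t.reroot_at_edge(mrca.edge, update_bipartitions=True)
    return t
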