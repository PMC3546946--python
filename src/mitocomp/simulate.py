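"""Synthetic mitogenome generator and sequence-evolution simulator.

The generator emulates a vertebrate mitogenome: a circular ~17.5 kb
molecule carrying 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one
control region in canonical vertebrate order, with nad6 and eight tRNAs on
the light strand, strand-asymmetric base composition (configurable AT/GC
skews on H-strand coding sequence), ATG starts, and the characteristic
mixture of complete (TAA/TAG/AGA/AGG) and incomplete (T/TA) stop codons.
Generated annotation tables validate cleanly against their genomes, so
every analysis stage has a self-contained test surface.

Evolution is simulated site-wise under TN93 (JC as the equal-rates special
case) along a user tree, with per-gene rate multipliers, and in codon mode
under an M0-style model (single-nucleotide codon moves, rate proportional
to the TN93 nucleotide factor times omega for nonsynonymous changes, stops
forbidden).  All randomness flows from one recorded seed; identical seeds
give identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from .composition import MITO_STOP_CODONS, SENSE_CODONS, VERTEBRATE_MITO_CODE
from .model import Feature, FeatureTable, MitoGenome, reverse_complement
from .selection import SubstitutionModel

__all__ = [
    "LayoutSpec",
    "SimTruth",
    "default_layout",
    "generate_annotated_genome",
    "evolve_along_tree",
    "evolve_codons",
    "evolve_annotated_genome",
    "random_cds",
    "DEFAULT_SIX_TAXON_TREE",
]

_NTS = "ACGT"
_NT_INDEX = {b: i for i, b in enumerate(_NTS)}

#: Six-taxon study topology: two outgroups sister to (ST,(XB,(XL,XV))).
DEFAULT_SIX_TAXON_TREE = (
    "((HB:0.15,PC:0.15):0.05,"
    "(ST:0.12,(XB:0.06,(XL:0.03,XV:0.03):0.03):0.04):0.05);"
)

#: canonical vertebrate mitochondrial feature plan: (name, kind, strand, length)
_DEFAULT_PLAN = (
    ("trnF", "tRNA", "H", 68),
    ("rrnS", "rRNA", "H", 947),
    ("trnV", "tRNA", "H", 70),
    ("rrnL", "rRNA", "H", 1635),
    ("trnL-UUR", "tRNA", "H", 75),
    ("nad1", "gene", "H", 969),
    ("trnI", "tRNA", "H", 71),
    ("trnQ", "tRNA", "L", 71),
    ("trnM", "tRNA", "H", 69),
    ("nad2", "gene", "H", 1038),
    ("trnW", "tRNA", "H", 69),
    ("trnA", "tRNA", "L", 71),
    ("trnN", "tRNA", "L", 75),
    ("trnC", "tRNA", "L", 66),
    ("trnY", "tRNA", "L", 72),
    ("cox1", "gene", "H", 1557),
    ("trnS-UCN", "tRNA", "L", 71),
    ("trnD", "tRNA", "H", 69),
    ("cox2", "gene", "H", 688),      # length mod 3 == 1 -> incomplete stop T
    ("trnK", "tRNA", "H", 74),
    ("atp8", "gene", "H", 168),
    ("atp6", "gene", "H", 684),
    ("cox3", "gene", "H", 784),      # incomplete stop T
    ("trnG", "tRNA", "H", 70),
    ("nad3", "gene", "H", 343),      # incomplete stop T
    ("trnR", "tRNA", "H", 70),
    ("nad4L", "gene", "H", 297),
    ("nad4", "gene", "H", 1378),     # incomplete stop T
    ("trnH", "tRNA", "H", 69),
    ("trnS-AGY", "tRNA", "H", 67),
    ("trnL-CUN", "tRNA", "H", 74),
    ("nad5", "gene", "H", 1818),
    ("nad6", "gene", "L", 519),
    ("trnE", "tRNA", "L", 70),
    ("cytb", "gene", "H", 1143),
    ("trnT", "tRNA", "H", 71),
    ("trnP", "tRNA", "L", 67),
)


@dataclass
class LayoutSpec:
    """Feature plan and compositional targets for genome generation.

    ``at_skew``/``gc_skew`` are targets for H-strand coding sequence
    (defaults match the strand asymmetry typical of frog mitogenomes:
    GC skew -0.32, AT skew -0.02, GC content 39.3%); the control region is
    AT-rich (60% AT by default).
    """

    plan: tuple = _DEFAULT_PLAN
    control_region_length: int = 1909
    gc_content: float = 0.393
    at_skew: float = -0.02
    gc_skew: float = -0.32
    control_region_at: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.at_skew) < 1 and abs(self.gc_skew) < 1):
            raise ValueError("|skew| must be < 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if any(length <= 0 for (_, _, _, length) in self.plan):
            raise ValueError("feature lengths must be positive")

    def base_frequencies(self) -> dict[str, float]:
        g = self.gc_content
        return {
            "A": (1 - g) / 2 * (1 + self.at_skew),
            "T": (1 - g) / 2 * (1 - self.at_skew),
            "G": g / 2 * (1 + self.gc_skew),
            "C": g / 2 * (1 - self.gc_skew),
        }


@dataclass
class SimTruth:
    """Ground truth for a simulation run: tree, rates, model, omega, seed."""

    tree_newick: str
    model: SubstitutionModel = field(default_factory=SubstitutionModel.jukes_cantor)
    gene_rates: dict[str, float] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.gene_rates.values()):
            raise ValueError("gene rate multipliers must be positive")
        if any(w < 0 for w in self.omega.values()):
            raise ValueError("omega values must be non-negative")
        tree = dendropy.Tree.get(data=self.tree_newick, schema="newick")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in truth tree")

    def write(self, tsv_path, newick_path) -> None:
        with open(newick_path, "w") as fh:
            fh.write(self.tree_newick.strip() + "\n")
        with open(tsv_path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"kappa_R\t{self.model.kappa_R}\n")
            fh.write(f"kappa_Y\t{self.model.kappa_Y}\n")
            for b in _NTS:
                fh.write(f"pi_{b}\t{self.model.pi[b]}\n")
            for g, r in self.gene_rates.items():
                fh.write(f"rate_{g}\t{r}\n")
            for g, w in self.omega.items():
                fh.write(f"omega_{g}\t{w}\n")


def default_layout(seed: int = 0, **overrides) -> LayoutSpec:
    """The canonical vertebrate plan with optional field overrides."""
    return LayoutSpec(seed=seed, **overrides)


def _calibrate_codon_freqs(target: dict[str, float],
                           n_iter: int = 60) -> dict[str, float]:
    """Sampling frequencies whose post-stop-rejection expectation hits target.

    Rejecting stop codons (TAA/TAG/AGA/AGG) depletes A and T relative to
    the raw sampling frequencies; a multiplicative fixed-point iteration
    compensates so the expected base composition of accepted codons equals
    the requested one.
    """
    q = dict(target)
    codons = [a + b + c for a in _NTS for b in _NTS for c in _NTS
              if a + b + c not in MITO_STOP_CODONS]
    for _ in range(n_iter):
        probs = np.array([q[c[0]] * q[c[1]] * q[c[2]] for c in codons])
        probs /= probs.sum()
        realized = {b: 0.0 for b in _NTS}
        for p, c in zip(probs, codons):
            for b in c:
                realized[b] += p / 3.0
        q = {b: q[b] * target[b] / max(realized[b], 1e-12) for b in _NTS}
        total = sum(q.values())
        q = {b: v / total for b, v in q.items()}
    return q


def _sample_bases(rng: np.random.Generator, n: int, freqs: dict[str, float]) -> str:
    p = np.array([freqs[b] for b in _NTS])
    p = p / p.sum()
    idx = rng.choice(4, size=n, p=p)
    return "".join(_NTS[i] for i in idx)


def random_cds(rng: np.random.Generator, length: int,
               freqs: dict[str, float] | None = None,
               start_codon: str = "ATG") -> str:
    """Random open reading frame of ``length`` nt under the mito code.

    The first codon is ``start_codon``; internal codons are sampled from
    the base frequencies with stop codons rejected; the terminal signal is
    a complete stop when ``length`` is a codon multiple, otherwise the
    incomplete stop T (remainder 1) or TA (remainder 2).
    """
    if length < 6:
        raise ValueError("CDS length must be at least 6 nt")
    freqs = freqs or {b: 0.25 for b in _NTS}
    rem = length % 3
    # first codon is the start; with a complete stop the last full codon is
    # the stop, otherwise all full codons after the start are internal.
    if rem == 0:
        n_internal = length // 3 - 2
        tail = str(rng.choice(["TAA", "TAG", "AGA", "AGG"],
                              p=[0.55, 0.2, 0.2, 0.05]))
    else:
        n_internal = length // 3 - 1
        tail = "T" if rem == 1 else "TA"
    codons = []
    while len(codons) < n_internal:
        c = _sample_bases(rng, 3, freqs)
        if c not in MITO_STOP_CODONS:
            codons.append(c)
    return start_codon + "".join(codons) + tail


def generate_annotated_genome(spec: LayoutSpec) -> tuple[MitoGenome, FeatureTable]:
    """Generate one annotated circular mitogenome from a layout spec.

    Features are laid out contiguously from position 1; genes are ORFs
    under the vertebrate mitochondrial code; L-strand features are
    generated in transcription sense and reverse-complemented into the
    genome.  The returned table validates cleanly against the genome.
    """
    from .composition import base_composition

    rng = np.random.default_rng(spec.seed)
    coding_freqs = _calibrate_codon_freqs(spec.base_frequencies())
    neutral_freqs = {"A": 0.30, "C": 0.24, "G": 0.21, "T": 0.25}
    cr_at = spec.control_region_at
    cr_freqs = {"A": cr_at / 2, "T": cr_at / 2,
                "G": (1 - cr_at) / 2, "C": (1 - cr_at) / 2}

    pieces: list[str] = []
    features: list[Feature] = []
    pos = 1
    plan = list(spec.plan) + [("D-loop", "control_region", "H",
                               spec.control_region_length)]
    for (name, kind, strand, length) in plan:
        if kind == "gene":
            sense = random_cds(rng, length, coding_freqs)
            start_codon = sense[:3]
            rem = length % 3
            stop = sense[-3:] if rem == 0 else sense[-rem:]
        elif kind == "control_region":
            sense = _sample_bases(rng, length, cr_freqs)
            start_codon = stop = ""
        else:
            sense = _sample_bases(rng, length, neutral_freqs)
            start_codon = stop = ""
        genomic = reverse_complement(sense) if strand == "L" else sense
        pieces.append(genomic)
        feature = Feature(
            kind=kind, name=name, strand=strand,
            start=pos, end=pos + length - 1, declared_length=length,
            start_codon=start_codon, stop_codon=stop,
        )
        pos += length
        features.append(feature)

    sequence = "".join(pieces)
    genome = MitoGenome(id=f"sim{spec.seed}", sequence=sequence,
                        species="synthetic", circular=True)
    for f in features:
        seq = sequence[f.start - 1:f.end]
        if f.strand == "L":
            seq = reverse_complement(seq)
        pct = base_composition(seq).percentages
        f.pct = {b: round(pct[b], 1) for b in "ACGT"}
    return genome, FeatureTable(genome_id=genome.id, features=features)


def _encode_nt(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX[b] for b in seq], dtype=np.int8)


def _evolve_states(rng: np.random.Generator, parent: np.ndarray,
                   Q: np.ndarray, t_per_site: np.ndarray) -> np.ndarray:
    """Evolve discrete states site-wise for per-site durations."""
    child = parent.copy()
    for t in np.unique(t_per_site):
        idx = np.nonzero(t_per_site == t)[0]
        if t == 0:
            continue
        P = expm(Q * t)
        P = np.clip(P, 0, None)
        P /= P.sum(axis=1, keepdims=True)
        cum = P.cumsum(axis=1)
        u = rng.random(len(idx))
        child[idx] = (u[:, None] > cum[parent[idx]]).sum(axis=1)
    return child


def _tree_and_paths(truth: SimTruth):
    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    expected = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            t1 = tree.taxon_namespace.get_taxon(a)
            t2 = tree.taxon_namespace.get_taxon(b)
            expected[(a, b)] = pdm.patristic_distance(t1, t2)
    return tree, expected


def evolve_along_tree(
    root: MitoGenome | str,
    truth: SimTruth,
    table: FeatureTable | None = None,
) -> dict:
    """Simulate nucleotide evolution of the root sequence along the tree.

    Per-gene rate multipliers from ``truth.gene_rates`` (matched to feature
    names of ``table``) scale branch lengths within gene intervals;
    unlisted sites evolve at rate 1.  The simulation is indel-free, so tip
    sequences double as an alignment.  Returns tips, the alignment and the
    true expected pairwise distances (tree path length; multiply by the
    local rate for per-region expectations).
    """
    seq = root.sequence if isinstance(root, MitoGenome) else root.upper()
    rng = np.random.default_rng(truth.seed)
    L = len(seq)
    rates = np.ones(L)
    if table is not None and truth.gene_rates:
        for f in table:
            if f.name in truth.gene_rates and not f.wraps:
                rates[f.start - 1:f.end] = truth.gene_rates[f.name]
    Q = truth.model.rate_matrix()

    tree, expected = _tree_and_paths(truth)
    root_states = _encode_nt(seq)
    states = {tree.seed_node: root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        states[node] = _evolve_states(rng, states[node.parent_node], Q, bl * rates)

    tips = {}
    for leaf in tree.leaf_node_iter():
        tips[leaf.taxon.label] = "".join(_NTS[i] for i in states[leaf])
    return {"tips": tips, "alignment": dict(tips),
            "expected_distances": expected, "rates": rates}


def _scale_tree(newick: str, factor: float) -> str:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree.as_string(schema="newick")


def evolve_annotated_genome(
    root: MitoGenome,
    table: FeatureTable,
    truth: SimTruth,
) -> dict:
    """Evolve a whole annotated genome into valid annotated tip genomes.

    Protein-coding genes evolve in codon (M0) mode with the start codon and
    the terminal stop signal held fixed, so every tip remains an ORF that
    validates cleanly; tRNAs, rRNAs and the control region evolve site-wise
    under the nucleotide model.  ``truth.gene_rates`` scales branch lengths
    per feature (any feature name), ``truth.omega`` sets per-gene omega
    (default 1).  Each feature uses an independent stream derived from
    ``truth.seed``.  Coordinates are preserved (indel-free), so each tip
    gets a copy of the annotation table with recomputed composition.
    """
    from .composition import base_composition
    from .model import extract_feature_sequence

    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    pieces: dict[str, list[str]] = {lab: [] for lab in labels}
    feats = table.sorted().features

    for idx, f in enumerate(feats):
        sub_seed = (truth.seed * 100003 + 7919 * idx + 1) % (2 ** 31)
        rate = truth.gene_rates.get(f.name, 1.0)
        newick = (_scale_tree(truth.tree_newick, rate)
                  if rate != 1.0 else truth.tree_newick)
        sense = extract_feature_sequence(root, f)
        if f.kind == "gene":
            rem = len(sense) % 3
            tail_len = rem if rem else 3
            head, core, tail = sense[:3], sense[3:len(sense) - tail_len], \
                sense[len(sense) - tail_len:]
            sub = SimTruth(tree_newick=newick, model=truth.model,
                           omega={f.name: truth.omega.get(f.name, 1.0)},
                           seed=sub_seed)
            tips = evolve_codons(core, sub, gene=f.name)["tips"]
            tip_seqs = {lab: head + tips[lab] + tail for lab in labels}
        else:
            sub = SimTruth(tree_newick=newick, model=truth.model, seed=sub_seed)
            tip_seqs = evolve_along_tree(sense, sub)["tips"]
        for lab in labels:
            s = tip_seqs[lab]
            pieces[lab].append(reverse_complement(s) if f.strand == "L" else s)

    genomes = {}
    tables = {}
    for lab in labels:
        seq = "".join(pieces[lab])
        genome = MitoGenome(id=lab, sequence=seq, species="synthetic",
                            circular=root.circular)
        tip_feats = []
        for f in feats:
            sense = seq[f.start - 1:f.end]
            if f.strand == "L":
                sense = reverse_complement(sense)
            pct = base_composition(sense).percentages
            tip_feats.append(Feature(
                kind=f.kind, name=f.name, strand=f.strand,
                start=f.start, end=f.end, declared_length=f.declared_length,
                start_codon=f.start_codon, stop_codon=f.stop_codon,
                pct={b: round(pct[b], 1) for b in "ACGT"},
            ))
        genomes[lab] = genome
        tables[lab] = FeatureTable(genome_id=lab, features=tip_feats)
    return {"genomes": genomes, "tables": tables, "truth": truth}


def _codon_generator(model: SubstitutionModel, omega: float) -> tuple[np.ndarray, np.ndarray]:
    """M0 rate matrix over the 60/61 sense codons (stops forbidden).

    q(c1 -> c2) for single-nucleotide moves is the TN93 nucleotide factor
    (kappa for transitions, target-base frequency) times omega when the
    change is nonsynonymous; scaled to one expected substitution per codon
    per unit branch length.  Also returns the stationary codon frequencies
    (F1x4: products of nucleotide frequencies, renormalised over sense
    codons).
    """
    n = len(SENSE_CODONS)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    pi_nt = model.pi
    pi_cod = np.array([pi_nt[c[0]] * pi_nt[c[1]] * pi_nt[c[2]]
                       for c in SENSE_CODONS])
    pi_cod /= pi_cod.sum()

    Q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in _NTS:
                if nt == c1[pos]:
                    continue
                c2 = c1[:pos] + nt + c1[pos + 1:]
                if c2 in MITO_STOP_CODONS:
                    continue
                j = idx[c2]
                pair = frozenset((c1[pos], nt))
                kappa = (model.kappa_R if pair == frozenset("AG")
                         else model.kappa_Y if pair == frozenset("CT") else 1.0)
                rate = kappa * pi_cod[j]
                if VERTEBRATE_MITO_CODE[c1] != VERTEBRATE_MITO_CODE[c2]:
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    stat = pi_cod / pi_cod.sum()
    scale = -(stat * np.diag(Q)).sum()
    return Q / scale, stat


def evolve_codons(
    root_cds: str | None,
    truth: SimTruth,
    gene: str = "gene",
    n_codons: int | None = None,
) -> dict:
    """Simulate codon (M0) evolution along the tree for one gene.

    ``root_cds`` must be internally stop-free and a codon multiple; when
    ``None``, a root of ``n_codons`` codons is drawn from the model's
    stationary codon frequencies.  Branch lengths are interpreted as
    expected substitutions per codon.  Returns tip CDS sequences (gap-free,
    in frame) and the omega used.
    """
    omega = truth.omega.get(gene, 1.0)
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(truth.seed)
    Q, stat = _codon_generator(truth.model, omega)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}

    if root_cds is None:
        if n_codons is None:
            raise ValueError("give root_cds or n_codons")
        root_states = rng.choice(len(SENSE_CODONS), size=n_codons, p=stat)
    else:
        root_cds = root_cds.upper()
        if len(root_cds) % 3 != 0:
            raise ValueError("root CDS length must be a codon multiple")
        codons = [root_cds[i:i + 3] for i in range(0, len(root_cds), 3)]
        bad = [c for c in codons if c not in idx]
        if bad:
            raise ValueError(f"root CDS contains stop/ambiguous codons: {bad[:3]}")
        root_states = np.array([idx[c] for c in codons])

    tree, expected = _tree_and_paths(truth)
    states = {tree.seed_node: root_states}
    ones = np.ones(len(root_states))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        states[node] = _evolve_states(rng, states[node.parent_node], Q, bl * ones)

    tips = {}
    for leaf in tree.leaf_node_iter():
        tips[leaf.taxon.label] = "".join(SENSE_CODONS[i] for i in states[leaf])
    return {"tips": tips, "omega": omega, "expected_distances": expected}
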