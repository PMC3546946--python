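"""Pairwise dN/dS estimation by codon-site counting.

Two estimators are provided, both for the vertebrate mitochondrial code:

* **NG86** — classic Nei-Gojobori counting: synonymous/nonsynonymous site
  fractions are averaged over the three codon positions with every
  single-nucleotide change weighted equally; multi-nucleotide codon
  differences are averaged over all substitution pathways that avoid stop
  codons; pS and pN receive a Jukes-Cantor multiple-hit correction.

* **MYN** — a modified Yang-Nielsen-style variant of the same counting
  scheme in which (i) site classification and (ii) pathway weighting use
  Tamura-Nei (TN93) mutation-rate factors (separate purine and pyrimidine
  transition/transversion ratios, target-base frequencies) estimated from
  the data, and (iii) the multiple-hit correction inverts the expected
  p-distance under the fitted TN93 rate matrix instead of assuming JC.
  With both kappas at 1 and uniform base frequencies every weight is equal
  and the TN93 matrix collapses to JC, so MYN reproduces NG86 exactly;
  this collapse identity is the method's correctness anchor.

ω = dN/dS classifies selection: purifying (ω < 1), neutral (ω = 1),
positive (ω > 1).  ω is undefined (not infinite) when dS = 0.
"""
from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .composition import MITO_STOP_CODONS, SENSE_CODONS, VERTEBRATE_MITO_CODE
from .divergence import jc_divergence

__all__ = [
    "CodonAlignment",
    "SubstitutionModel",
    "KaKsResult",
    "ng86_pairwise",
    "myn_pairwise",
    "estimate_tn93",
    "classify_selection",
    "kaks_table",
]

_NTS = "ACGT"
MIN_KAPPA = 1e-3
SATURATION_P = 0.75


@dataclass
class CodonAlignment:
    """Gap-aligned, in-frame CDS set for one gene.

    Aligned length must be a codon multiple, gaps must occupy whole codons,
    and no ungapped sequence may contain an internal stop codon.
    """

    sequences: dict[str, str]
    gene: str = ""
    code: int = 2

    def __post_init__(self) -> None:
        if self.code != 2:
            raise ValueError("only the vertebrate mitochondrial code is supported")
        if len(self.sequences) < 2:
            raise ValueError("codon alignment needs at least two sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths: {lengths}")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError(f"aligned length {L} not divisible by 3")
        for label, seq in self.sequences.items():
            seq = seq.upper()
            self.sequences[label] = seq
            for i in range(0, L, 3):
                codon = seq[i:i + 3]
                if "-" in codon:
                    if codon != "---":
                        raise ValueError(
                            f"{label}: gap not in whole codons at {i + 1}")
                elif codon in MITO_STOP_CODONS and i < L - 3:
                    raise ValueError(
                        f"{label}: internal stop codon {codon} at codon "
                        f"{i // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    @classmethod
    def from_cds_set(cls, sequences: dict[str, str], gene: str = "") -> "CodonAlignment":
        """Build from unaligned equal-length CDSs.

        Incomplete terminal stops (length mod 3 of 1 or 2) are completed by
        A-padding, then any terminal stop codon is removed so only sense
        codons are compared.
        """
        prepared = {}
        for label, seq in sequences.items():
            seq = seq.upper()
            rem = len(seq) % 3
            if rem:
                seq += "A" * (3 - rem)
            if seq[-3:] in MITO_STOP_CODONS:
                seq = seq[:-3]
            prepared[label] = seq
        return cls(prepared, gene=gene)


@dataclass
class SubstitutionModel:
    """TN93 parameters: purine/pyrimidine transition ratios + base frequencies."""

    kappa_R: float
    kappa_Y: float
    pi: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kappa_R <= 0 or self.kappa_Y <= 0:
            raise ValueError("rate ratios must be positive")
        total = sum(self.pi.values())
        if abs(total - 1.0) > 1e-8 or min(self.pi.values()) <= 0:
            raise ValueError("base frequencies must be positive and sum to 1")

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls(1.0, 1.0, {b: 0.25 for b in _NTS})

    def rate_matrix(self) -> np.ndarray:
        """TN93 rate matrix (ACGT order) scaled to one substitution per unit time."""
        pi = np.array([self.pi[b] for b in _NTS])
        Q = np.zeros((4, 4))
        for i, x in enumerate(_NTS):
            for j, y in enumerate(_NTS):
                if i == j:
                    continue
                Q[i, j] = pi[j] * _change_kappa(x, y, self.kappa_R, self.kappa_Y)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def expected_p(self, d: float) -> float:
        """Expected p-distance between two sequences at divergence ``d``."""
        pi = np.array([self.pi[b] for b in _NTS])
        P = expm(self.rate_matrix() * d)
        return float(1.0 - (pi * np.diag(P)).sum())

    def correct_distance(self, p: float) -> float:
        """Invert the expected p-distance curve; ``nan`` beyond saturation."""
        if p <= 0:
            return 0.0
        pi = np.array([self.pi[b] for b in _NTS])
        p_max = 1.0 - float((pi ** 2).sum())
        if p >= p_max * (1 - 1e-9):
            return math.nan
        hi = 1.0
        while self.expected_p(hi) < p and hi < 1e3:
            hi *= 2.0
        if self.expected_p(hi) < p:
            return math.nan
        return float(brentq(lambda d: self.expected_p(d) - p, 0.0, hi,
                            xtol=1e-12, rtol=1e-14))


@dataclass
class KaKsResult:
    """dN/dS estimate for one gene and one taxon pair."""

    gene: str
    pair: tuple[str, str]
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    category: str
    n_codons: int
    saturated: bool = False


def _change_kappa(x: str, y: str, kappa_R: float, kappa_Y: float) -> float:
    pair = frozenset((x, y))
    if pair == frozenset("AG"):
        return kappa_R
    if pair == frozenset("CT"):
        return kappa_Y
    return 1.0


def _step_weight(x: str, y: str, model: SubstitutionModel | None) -> float:
    """Mutation-rate weight of a single-nucleotide change x -> y."""
    if model is None:
        return 1.0
    return _change_kappa(x, y, model.kappa_R, model.kappa_Y) * model.pi[y]


def _is_synonymous(c1: str, c2: str) -> bool:
    return VERTEBRATE_MITO_CODE[c1] == VERTEBRATE_MITO_CODE[c2]


def _site_counts(codon: str, model: SubstitutionModel | None) -> float:
    """Synonymous site count S for one codon (N = 3 - S).

    Each position contributes the rate-weighted fraction of non-stop
    single-nucleotide changes that are synonymous; changes producing stop
    codons are excluded from numerator and denominator.
    """
    s_total = 0.0
    for pos in range(3):
        syn_w = 0.0
        all_w = 0.0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in MITO_STOP_CODONS:
                continue
            w = _step_weight(codon[pos], nt, model)
            all_w += w
            if _is_synonymous(codon, alt):
                syn_w += w
        if all_w > 0:
            s_total += syn_w / all_w
    return s_total


@lru_cache(maxsize=None)
def _ng86_site_counts(codon: str) -> float:
    return _site_counts(codon, None)


def _pathways(c1: str, c2: str):
    """All direct substitution pathways c1 -> c2 avoiding stop intermediates.

    Yields lists of (from_codon, to_codon) steps.  Endpoints are assumed to
    be sense codons.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in permutations(diff):
        cur = c1
        steps = []
        legal = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in MITO_STOP_CODONS and nxt != c2:
                legal = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if legal:
            yield steps


def _shortest_detours(c1: str, c2: str):
    """All shortest paths c1 -> c2 through sense codons (stop-free).

    Used only for codon pairs whose every direct pathway crosses a stop
    codon (e.g. AAA <-> TGA under the mitochondrial code).
    """
    neighbours = {}
    for c in SENSE_CODONS:
        nb = []
        for pos in range(3):
            for nt in _NTS:
                if nt != c[pos]:
                    alt = c[:pos] + nt + c[pos + 1:]
                    if alt not in MITO_STOP_CODONS:
                        nb.append(alt)
        neighbours[c] = nb

    dist = {c1: 0}
    preds: dict[str, list[str]] = {c1: []}
    queue = deque([c1])
    while queue:
        cur = queue.popleft()
        if cur == c2:
            break
        for nxt in neighbours[cur]:
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                preds[nxt] = [cur]
                queue.append(nxt)
            elif dist[nxt] == dist[cur] + 1:
                preds[nxt].append(cur)

    paths = []

    def backtrack(node, suffix):
        if node == c1:
            paths.append([c1] + suffix)
            return
        for p in preds[node]:
            backtrack(p, [node] + suffix)

    backtrack(c2, [])
    for path in paths:
        yield list(zip(path[:-1], path[1:]))


def _pair_differences(c1: str, c2: str,
                      model: SubstitutionModel | None) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) for one codon pair.

    Pathways are weighted by the product of their step mutation weights
    (equal weights for NG86).  When no direct pathway avoids stop codons the
    shortest stop-free detour classifies the steps and the per-step
    synonymous fraction is rescaled to the observed number of nucleotide
    differences, so Sd + Nd always equals the observed differences.
    """
    ndiff = sum(a != b for a, b in zip(c1, c2))
    if ndiff == 0:
        return 0.0, 0.0
    total_w = 0.0
    sd_w = 0.0
    nsteps = None
    for steps in _pathways(c1, c2):
        w = 1.0
        sd = 0.0
        for (a, b) in steps:
            pos = next(i for i in range(3) if a[i] != b[i])
            w *= _step_weight(a[pos], b[pos], model)
            if _is_synonymous(a, b):
                sd += 1.0
        total_w += w
        sd_w += w * sd
        nsteps = len(steps)
    if total_w == 0.0:
        for steps in _shortest_detours(c1, c2):
            w = 1.0
            sd = 0.0
            for (a, b) in steps:
                pos = next(i for i in range(3) if a[i] != b[i])
                w *= _step_weight(a[pos], b[pos], model)
                if _is_synonymous(a, b):
                    sd += 1.0
            total_w += w * 1.0
            sd_w += w * (sd / len(steps)) * ndiff   # rescale to observed diffs
            nsteps = ndiff
        if total_w == 0.0:          # unreachable in practice
            return 0.0, float(ndiff)
        sd_mean = sd_w / total_w
        return sd_mean, ndiff - sd_mean
    sd_mean = sd_w / total_w
    return sd_mean, nsteps - sd_mean


@lru_cache(maxsize=None)
def _ng86_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    return _pair_differences(c1, c2, None)


def _comparable_codons(aln: CodonAlignment, pair: tuple[str, str]):
    a = aln.sequences[pair[0]]
    b = aln.sequences[pair[1]]
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if set(ca) <= set(_NTS) and set(cb) <= set(_NTS):
            if ca not in MITO_STOP_CODONS and cb not in MITO_STOP_CODONS:
                yield ca, cb


def _counting(aln: CodonAlignment, pair: tuple[str, str],
              model: SubstitutionModel | None, method: str) -> KaKsResult:
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in _comparable_codons(aln, pair):
        if model is None:
            s_a, s_b = _ng86_site_counts(ca), _ng86_site_counts(cb)
            sd, nd = _ng86_pair_differences(ca, cb)
        else:
            s_a, s_b = _site_counts(ca, model), _site_counts(cb, model)
            sd, nd = _pair_differences(ca, cb, model)
        S += 0.5 * (s_a + s_b)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"no comparable codons between {pair[0]} and {pair[1]}")
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    if model is None:
        dS = jc_divergence(pS) if pS < SATURATION_P else math.nan
        dN = jc_divergence(pN) if pN < SATURATION_P else math.nan
    else:
        dS = model.correct_distance(pS)
        dN = model.correct_distance(pN)
    saturated = math.isnan(dS) or math.isnan(dN)

    omega: float | None
    if saturated or dS == 0.0:
        omega = None
    else:
        omega = dN / dS
    return KaKsResult(
        gene=aln.gene, pair=tuple(pair), method=method,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
        omega=omega,
        category=classify_selection_value(omega),
        n_codons=n_codons, saturated=saturated,
    )


def ng86_pairwise(aln: CodonAlignment, pair: tuple[str, str]) -> KaKsResult:
    """Nei-Gojobori (1986) counting estimate of dN and dS for one pair."""
    return _counting(aln, pair, None, "NG86")


def myn_pairwise(
    aln: CodonAlignment,
    pair: tuple[str, str],
    model: SubstitutionModel | None = None,
) -> KaKsResult:
    """TN93-weighted counting estimate (modified Yang-Nielsen style).

    The substitution model is estimated from the whole alignment with
    :func:`estimate_tn93` unless supplied.
    """
    if model is None:
        model = estimate_tn93(aln)
    return _counting(aln, pair, model, "MYN")


def estimate_tn93(alignment) -> SubstitutionModel:
    """Moment estimate of TN93 parameters from aligned nucleotide data.

    Accepts a :class:`CodonAlignment` or a ``{label: aligned seq}`` mapping.
    Base frequencies are observed frequencies; the transition/transversion
    ratios are recovered by inverting the TN93 expected proportions of
    purine transitions (P1), pyrimidine transitions (P2) and transversions
    (Q), pooled over all sequence pairs.  When the formulas are undefined
    (saturation, no transversions, degenerate data) the affected ratio
    falls back to 1 with a warning note.
    """
    seqs = alignment.sequences if isinstance(alignment, CodonAlignment) else alignment
    labels = list(seqs)
    counts = {b: 0 for b in _NTS}
    for s in seqs.values():
        for b in _NTS:
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in alignment")
    # tiny pseudocount keeps frequencies strictly positive
    pi = {b: (counts[b] + 0.5) / (total + 2.0) for b in _NTS}

    n_sites = n_P1 = n_P2 = n_Q = 0
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    for la, lb in combinations(labels, 2):
        for x, y in zip(seqs[la], seqs[lb]):
            if x not in _NTS or y not in _NTS:
                continue
            n_sites += 1
            if x == y:
                continue
            if {x, y} <= purines:
                n_P1 += 1
            elif {x, y} <= pyrimidines:
                n_P2 += 1
            else:
                n_Q += 1
    notes: list[str] = []
    if n_sites < 100:
        notes.append(f"only {n_sites} comparable sites; estimates unstable")
        warnings.warn(notes[-1])
    if n_sites == 0:
        return SubstitutionModel(1.0, 1.0, pi, notes)

    P1, P2, Q = n_P1 / n_sites, n_P2 / n_sites, n_Q / n_sites
    gR = pi["A"] + pi["G"]
    gY = pi["C"] + pi["T"]

    def _fallback(msg: str) -> SubstitutionModel:
        notes.append(msg)
        warnings.warn(msg)
        return SubstitutionModel(1.0, 1.0, pi, notes)

    e3 = 1.0 - Q / (2.0 * gR * gY)
    if e3 <= 0:
        return _fallback("transversion saturation; rate ratios undefined")
    beta_t = -0.5 * math.log(e3)
    if beta_t <= 0:
        return _fallback("no transversions observed; rate ratios undefined")
    e1 = gR + gY * e3 - gR * P1 / (2.0 * pi["A"] * pi["G"])
    e2 = gY + gR * e3 - gY * P2 / (2.0 * pi["C"] * pi["T"])
    if e1 <= 0 or e2 <= 0:
        return _fallback("transition saturation; rate ratios undefined")
    alpha1_t = (-0.5 * math.log(e1) - gY * beta_t) / gR
    alpha2_t = (-0.5 * math.log(e2) - gR * beta_t) / gY
    kappa_R = alpha1_t / beta_t
    kappa_Y = alpha2_t / beta_t
    if kappa_R < MIN_KAPPA:
        notes.append(f"kappa_R clamped to lower bound {MIN_KAPPA}")
        warnings.warn(notes[-1])
        kappa_R = MIN_KAPPA
    if kappa_Y < MIN_KAPPA:
        notes.append(f"kappa_Y clamped to lower bound {MIN_KAPPA}")
        warnings.warn(notes[-1])
        kappa_Y = MIN_KAPPA
    return SubstitutionModel(kappa_R, kappa_Y, pi, notes)


def classify_selection_value(omega: float | None,
                             neutral_band: float = 0.05) -> str:
    if omega is None or math.isnan(omega):
        return "undetermined"
    if omega < 1.0 - neutral_band:
        return "negative"
    if omega > 1.0 + neutral_band:
        return "positive"
    return "neutral"


def classify_selection(result: KaKsResult, neutral_band: float = 0.05) -> str:
    """Selection category from ω: negative (< 1-band), positive (> 1+band),
    neutral within the band, undetermined when ω is undefined."""
    return classify_selection_value(result.omega, neutral_band)


def kaks_table(results: list[KaKsResult], path) -> None:
    """Write per-gene, per-pair dN/dS results as TSV."""
    with open(path, "w") as fh:
        fh.write("gene\ttaxonA\ttaxonB\tmethod\tS\tN\tSd\tNd\tdS\tdN\tomega\tcategory\n")
        for r in results:
            omega = "NA" if r.omega is None else f"{r.omega:.4f}"
            ds = "NA" if math.isnan(r.dS) else f"{r.dS:.4f}"
            dn = "NA" if math.isnan(r.dN) else f"{r.dN:.4f}"
            fh.write(
                f"{r.gene}\t{r.pair[0]}\t{r.pair[1]}\t{r.method}\t"
                f"{r.S:.2f}\t{r.N:.2f}\t{r.Sd:.2f}\t{r.Nd:.2f}\t"
                f"{ds}\t{dn}\t{omega}\t{r.category}\n")
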