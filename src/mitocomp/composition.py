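"""Base composition, strand-skew indices, codon usage and mitochondrial translation.

Strand skews measure compositional asymmetry between the heavy (H) and
light (L) strands of mtDNA::

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the reported strand.  A negative GC skew means G is
preferentially located on the other (complementary) strand.  Translation
uses the vertebrate mitochondrial genetic code (NCBI translation table 2):
TGA encodes Trp, ATA encodes Met, and AGA/AGG are stops; genes frequently
end on an incomplete stop (T or TA) completed to TAA by polyadenylation of
the transcript.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import IUPAC_DNA, Feature, FeatureTable, MitoGenome, extract_feature_sequence

__all__ = [
    "VERTEBRATE_MITO_CODE",
    "CompositionSummary",
    "CodonUsage",
    "base_composition",
    "skew_indices",
    "codon_usage",
    "translate_mito",
    "classify_stop",
    "hstrand_coding_skews",
]

_BASES = "TCAG"
# NCBI translation table 2 in TCAG codon order.
_MITO_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"

#: codon -> one-letter amino acid, '*' for stop (vertebrate mitochondrial code)
VERTEBRATE_MITO_CODE: dict[str, str] = {
    b1 + b2 + b3: _MITO_AA[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

MITO_STOP_CODONS = frozenset(c for c, aa in VERTEBRATE_MITO_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in VERTEBRATE_MITO_CODE if c not in MITO_STOP_CODONS))


@dataclass
class CompositionSummary:
    """Unambiguous base counts, percentages and strand-skew indices."""

    counts: dict[str, int]
    percentages: dict[str, float]
    at_skew: float | None
    gc_skew: float | None
    n_sites: int


@dataclass
class CodonUsage:
    """Codon counts and start/stop conventions for one CDS."""

    counts: dict[str, int]
    initiation_codon: str
    termination: str            # complete triplet, or incomplete "TA"/"T"
    termination_class: str      # complete | incomplete | invalid
    frame_remainder: int        # 0, 1 or 2 trailing nt
    n_ambiguous_codons: int


def base_composition(seq: str) -> CompositionSummary:
    """Count A/C/G/T over the unambiguous positions of ``seq``.

    Ambiguity codes (N, R, Y, ...) are excluded from counts and from the
    percentage denominator.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    pct = {b: 100.0 * counts[b] / n for b in "ACGT"}
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    at_skew = (counts["A"] - counts["T"]) / at if at > 0 else None
    gc_skew = (counts["G"] - counts["C"]) / gc if gc > 0 else None
    return CompositionSummary(counts, pct, at_skew, gc_skew, n)


def skew_indices(seq_or_summary) -> dict:
    """AT and GC skew of a sequence or a precomputed summary.

    Returns ``{"AT_skew": x, "GC_skew": y}``; an index is ``None`` when its
    denominator (A+T or G+C) is zero.
    """
    summ = (seq_or_summary if isinstance(seq_or_summary, CompositionSummary)
            else base_composition(seq_or_summary))
    return {"AT_skew": summ.at_skew, "GC_skew": summ.gc_skew}


def classify_stop(fragment: str) -> str:
    """Classify a 1-3 nt terminal fragment as a mitochondrial stop signal.

    TAA/TAG/AGA/AGG are complete stops; T and TA are incomplete stops
    (completed by transcript polyadenylation); anything else is invalid.
    """
    frag = fragment.upper()
    if not 1 <= len(frag) <= 3:
        raise ValueError("stop fragment must be 1-3 nt")
    if frag in MITO_STOP_CODONS:
        return "complete"
    if frag in ("T", "TA"):
        return "incomplete"
    return "invalid"


def codon_usage(cds: str, code: int = 2) -> CodonUsage:
    """Codon counts for a CDS read in frame from its first nucleotide.

    A trailing 1- or 2-nt remainder is interpreted as a candidate incomplete
    stop.  Codons containing ambiguity codes are skipped and tallied in
    ``n_ambiguous_codons``.
    """
    if code != 2:
        raise ValueError("only the vertebrate mitochondrial code (table 2) is supported")
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    remainder = len(cds) % 3
    counts: dict[str, int] = {}
    n_ambiguous = 0
    for i in range(0, len(cds) - remainder, 3):
        codon = cds[i:i + 3]
        if set(codon) <= set("ACGT"):
            counts[codon] = counts.get(codon, 0) + 1
        else:
            n_ambiguous += 1
    if remainder:
        termination = cds[-remainder:]
    else:
        termination = cds[-3:]
    return CodonUsage(
        counts=counts,
        initiation_codon=cds[:3],
        termination=termination,
        termination_class=classify_stop(termination),
        frame_remainder=remainder,
        n_ambiguous_codons=n_ambiguous,
    )


def translate_mito(cds: str, allow_internal_stops: bool = False) -> str:
    """Translate complete triplets under the vertebrate mitochondrial code.

    The terminal stop (if the last complete codon is a stop) is dropped.
    Internal stops raise by default; under ``allow_internal_stops`` they are
    rendered as ``*``.  Codons containing ambiguity codes yield ``X``.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    n_codons = len(cds) // 3
    residues = []
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        aa = VERTEBRATE_MITO_CODE.get(codon, "X")
        if aa == "*":
            if i == n_codons - 1:
                break                       # terminal stop dropped
            if not allow_internal_stops:
                raise ValueError(
                    f"internal stop codon {codon} at codon position {i + 1}")
        residues.append(aa)
    return "".join(residues)


def hstrand_coding_skews(
    genome: MitoGenome,
    table: FeatureTable,
    method: str = "pooled",
    include_light_strand: bool = False,
) -> dict:
    """Species-level composition/skew summary over protein-coding genes.

    By default only H-strand genes enter (the single L-strand gene, nad6, is
    excluded, matching the usual "H-strand protein-coding genes" summaries);
    ``include_light_strand`` adds it, read in its own transcription sense.

    ``method="pooled"`` concatenates the gene sequences before computing
    (length-weighted); ``method="per_gene_mean"`` averages per-gene values
    unweighted.  Published species tables do not state which convention they
    use, so both are available.
    """
    genes: list[Feature] = [
        f for f in table.by_kind("gene")
        if include_light_strand or f.strand == "H"
    ]
    if not genes:
        raise ValueError("no protein-coding genes selected")
    seqs = [extract_feature_sequence(genome, f) for f in genes]
    if method == "pooled":
        summ = base_composition("".join(seqs))
        pct_at = summ.percentages["A"] + summ.percentages["T"]
        pct_gc = summ.percentages["G"] + summ.percentages["C"]
        return {"pct_AT": pct_at, "pct_GC": pct_gc,
                "AT_skew": summ.at_skew, "GC_skew": summ.gc_skew,
                "method": "pooled", "n_genes": len(genes)}
    if method == "per_gene_mean":
        summs = [base_composition(s) for s in seqs]
        n = len(summs)
        return {
            "pct_AT": sum(s.percentages["A"] + s.percentages["T"] for s in summs) / n,
            "pct_GC": sum(s.percentages["G"] + s.percentages["C"] for s in summs) / n,
            "AT_skew": sum(s.at_skew for s in summs) / n,
            "GC_skew": sum(s.gc_skew for s in summs) / n,
            "method": "per_gene_mean", "n_genes": n,
        }
    raise ValueError("method must be 'pooled' or 'per_gene_mean'")
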