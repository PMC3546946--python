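"""Data model for circular mitogenomes, annotation tables and read statistics.

Coordinates are 1-based and fully inclusive throughout, matching the
convention of published mitogenome annotation tables.  A feature may wrap
the origin of a circular genome (``end < start``); wrapping is illegal on
linear genomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "IUPAC_DNA",
    "MitoGenome",
    "Feature",
    "FeatureTable",
    "ReadStats",
    "Violation",
    "PROTEIN_CODING_GENES",
    "extract_feature_sequence",
    "validate_feature_table",
    "genome_length_from_table",
    "compare_gene_order",
    "coverage_summary",
]

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Canonical names of the 13 vertebrate mitochondrial protein-coding genes.
PROTEIN_CODING_GENES = (
    "nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nad3", "nad4L", "nad4", "nad5", "nad6", "cytb",
)

VALID_START_CODONS = frozenset({"ATG", "GTG"})
VALID_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG", "TA", "T"})

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MitoGenome:
    """A single (usually circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    species: str = ""
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"genome {self.id!r}: non-IUPAC character {ch!r} at position {i + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """One annotated feature: gene, tRNA, rRNA or control region.

    ``start``/``end`` are 1-based inclusive on the H-strand coordinate
    system; L-strand features keep H-strand coordinates and are flagged by
    ``strand='L'``.
    """

    kind: str                 # gene | tRNA | rRNA | control_region
    name: str
    strand: str               # H | L
    start: int
    end: int
    declared_length: int
    start_codon: str = ""
    stop_codon: str = ""
    pct: dict[str, float] | None = None   # published A/C/G/T percentages

    def __post_init__(self) -> None:
        if self.kind not in {"gene", "tRNA", "rRNA", "control_region"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in {"H", "L"}:
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(
                f"feature {self.name!r}: coordinates are 1-based, got "
                f"{self.start}..{self.end}"
            )

    @property
    def wraps(self) -> bool:
        """True when the feature crosses the origin (end < start)."""
        return self.end < self.start

    def span(self, genome_length: int) -> int:
        """Length in nt implied by the coordinates (handles origin wrap)."""
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    """Ordered annotation table for one genome (the in-memory printed table)."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def sorted(self) -> "FeatureTable":
        feats = sorted(self.features, key=lambda f: (f.start, f.end))
        return FeatureTable(self.genome_id, feats)

    def by_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in table {self.genome_id!r}")


@dataclass
class ReadStats:
    """Sequencing-run summary for one assembled genome."""

    genome_id: str
    total_reads: int
    mapped_reads: int
    total_nt: int
    mapped_nt: int
    genome_length: int

    def __post_init__(self) -> None:
        if min(self.total_reads, self.mapped_reads, self.total_nt,
               self.mapped_nt, self.genome_length) < 0:
            raise ValueError("read statistics must be non-negative")
        if self.mapped_reads > self.total_reads:
            raise ValueError("mapped_reads exceeds total_reads")
        if self.mapped_nt > self.total_nt:
            raise ValueError("mapped_nt exceeds total_nt")


@dataclass
class Violation:
    """One failed validation check.  Violations are data, not exceptions."""

    code: str
    severity: str            # ERROR | WARN | INFO
    feature: str
    message: str


def extract_feature_sequence(genome: MitoGenome, feature: Feature) -> str:
    """Feature subsequence in transcription sense.

    H-strand features return the genome subsequence as-is; L-strand features
    return its reverse complement.  Wrapping features concatenate the suffix
    from ``start`` with the prefix up to ``end`` (circular genomes only).
    """
    L = genome.length
    if not (1 <= feature.start <= L and 1 <= feature.end <= L):
        raise ValueError(
            f"feature {feature.name!r} coordinates {feature.start}..{feature.end} "
            f"out of range for genome of length {L}"
        )
    if feature.wraps:
        if not genome.circular:
            raise ValueError(
                f"feature {feature.name!r} wraps the origin but genome "
                f"{genome.id!r} is linear"
            )
        seq = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        seq = genome.sequence[feature.start - 1:feature.end]
    if feature.strand == "L":
        seq = reverse_complement(seq)
    return seq


def genome_length_from_table(table: FeatureTable) -> int:
    """Genome length inferred as the maximum feature end coordinate.

    Valid when the last feature (typically the control region) reaches the
    final base and no feature wraps the origin.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    for f in table:
        if f.wraps:
            raise ValueError(
                f"feature {f.name!r} wraps the origin; genome length cannot be "
                "inferred from coordinates"
            )
    return max(f.end for f in table)


def compare_gene_order(a: FeatureTable, b: FeatureTable) -> dict:
    """Compare feature order and strandedness between two tables.

    The signature is the list of ``(name, strand)`` in table order with
    names lower-cased (Leu/Ser anticodon labels are part of the name and must
    match exactly, case aside).  Coordinates are ignored entirely: published
    tables occasionally carry coordinate typos (e.g. a tRNA duplicating a
    neighbour's span) that should not defeat an order comparison, and the
    row order of a curated table is itself the asserted gene order.
    """
    sig_a = [(f.name.lower(), f.strand) for f in a]
    sig_b = [(f.name.lower(), f.strand) for f in b]
    identical = sig_a == sig_b
    first_divergence = None
    if not identical:
        for i, (x, y) in enumerate(zip(sig_a, sig_b)):
            if x != y:
                first_divergence = (i, x, y)
                break
        else:
            i = min(len(sig_a), len(sig_b))
            first_divergence = (
                i,
                sig_a[i] if i < len(sig_a) else None,
                sig_b[i] if i < len(sig_b) else None,
            )
    return {
        "identical": identical,
        "signature_a": sig_a,
        "signature_b": sig_b,
        "first_divergence": first_divergence,
    }


def coverage_summary(stats: ReadStats) -> dict:
    """Mapping percentages and mean depth of coverage for one run.

    mean DOC = mapped nucleotides / genome length, rounded to the nearest
    integer; percentages are rounded to 2 decimal places.
    """
    if stats.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if stats.total_reads <= 0 or stats.total_nt <= 0:
        raise ValueError("total read counts must be positive")
    return {
        "pct_reads_mapped": round(100.0 * stats.mapped_reads / stats.total_reads, 2),
        "pct_nt_mapped": round(100.0 * stats.mapped_nt / stats.total_nt, 2),
        "mean_doc": int(round(stats.mapped_nt / stats.genome_length)),
    }


def validate_feature_table(
    table: FeatureTable,
    genome: MitoGenome | None = None,
    composition_tolerance: float = 0.1,
) -> list[Violation]:
    """Run all annotation checks; return one :class:`Violation` per failure.

    Checks: coordinates in range, declared length vs coordinate span, gene
    start/stop codon conventions, published vs recomputed base composition
    (within ``composition_tolerance`` percentage points, genome required),
    control-region count, duplicate coordinate spans (WARN) and feature
    overlaps (INFO — overlaps such as atp8/atp6 are biological).
    """
    from . import composition as _comp   # local import; composition is model-free

    out: list[Violation] = []
    L = genome.length if genome is not None else None

    for f in table:
        if L is not None and not (1 <= f.start <= L and 1 <= f.end <= L):
            out.append(Violation(
                "COORD_RANGE", "ERROR", f.name,
                f"coordinates {f.start}..{f.end} outside genome of length {L}",
            ))
            continue
        span_L = L if L is not None else max(g.end for g in table)
        if f.wraps and (genome is not None and not genome.circular):
            out.append(Violation(
                "WRAP_ON_LINEAR", "ERROR", f.name,
                "feature wraps the origin of a linear genome",
            ))
        span = f.span(span_L)
        if span != f.declared_length:
            out.append(Violation(
                "LENGTH_MISMATCH", "ERROR", f.name,
                f"declared length {f.declared_length} != coordinate span {span}",
            ))
        if f.kind == "gene":
            if f.start_codon not in VALID_START_CODONS:
                out.append(Violation(
                    "START_CODON", "ERROR", f.name,
                    f"start codon {f.start_codon!r} not in "
                    f"{sorted(VALID_START_CODONS)}",
                ))
            if f.stop_codon not in VALID_STOP_CODONS:
                out.append(Violation(
                    "STOP_CODON", "ERROR", f.name,
                    f"stop codon {f.stop_codon!r} not a complete (TAA/TAG/AGA/AGG) "
                    "or incomplete (TA/T) mitochondrial stop",
                ))
        if genome is not None and f.pct is not None:
            try:
                seq = extract_feature_sequence(genome, f)
            except ValueError:
                seq = ""
            if seq:
                summ = _comp.base_composition(seq)
                for base in "ACGT":
                    delta = abs(summ.percentages[base] - f.pct[base])
                    if delta > composition_tolerance + 1e-9:
                        out.append(Violation(
                            "COMPOSITION", "ERROR", f.name,
                            f"published {base}% {f.pct[base]:.1f} differs from "
                            f"recomputed {summ.percentages[base]:.1f} by "
                            f"{delta:.2f} (> {composition_tolerance})",
                        ))

    n_cr = len(table.by_kind("control_region"))
    if n_cr != 1:
        out.append(Violation(
            "CONTROL_REGION_COUNT", "WARN", "-",
            f"expected exactly one control region, found {n_cr}",
        ))

    seen_spans: dict[tuple[int, int], str] = {}
    feats = table.sorted().features
    for f in feats:
        key = (f.start, f.end)
        if key in seen_spans:
            out.append(Violation(
                "DUPLICATE_SPAN", "WARN", f.name,
                f"coordinates {f.start}..{f.end} duplicate feature "
                f"{seen_spans[key]!r} (suspected annotation typo)",
            ))
        else:
            seen_spans[key] = f.name
    for prev, cur in zip(feats, feats[1:]):
        if not prev.wraps and not cur.wraps and cur.start <= prev.end:
            overlap = prev.end - cur.start + 1
            out.append(Violation(
                "OVERLAP", "INFO", cur.name,
                f"overlaps {prev.name!r} by {overlap} nt",
            ))
    return out
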