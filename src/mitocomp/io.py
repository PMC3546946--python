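"""File I/O: FASTA genomes/alignments, annotation-table TSV, read-stats TSV.

The annotation-table dialect is UTF-8, tab-separated, ``#`` comments, with a
required header::

    genome_id kind name strand start end declared_length start_codon
    stop_codon pctA pctC pctG pctT

Legacy tables that mark L-strand features with a ``[C]`` token in the name
field are accepted; the token is stripped and mapped to ``strand=L``.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

from Bio import SeqIO

from .model import (
    Feature,
    FeatureTable,
    MitoGenome,
    ReadStats,
    Violation,
)

__all__ = [
    "read_genome_fasta",
    "write_genome_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_read_stats",
    "write_violations",
    "read_alignment_fasta",
    "load_published_feature_table",
    "load_published_read_stats",
    "PUBLISHED_SPECIES",
]

PUBLISHED_SPECIES = ("XL", "ST", "XB", "XV")

_TABLE_COLUMNS = [
    "genome_id", "kind", "name", "strand", "start", "end", "declared_length",
    "start_codon", "stop_codon", "pctA", "pctC", "pctG", "pctT",
]


def read_genome_fasta(path: str | Path) -> list[MitoGenome]:
    """Read genomes from FASTA; one :class:`MitoGenome` per record.

    Circularity is taken from a ``circular`` token on the description line
    (default: circular).  Non-IUPAC characters are rejected with a position
    report (via :class:`MitoGenome` validation).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    genomes = []
    for rec in records:
        tokens = rec.description.lower().split()
        circular = True
        if "linear" in tokens:
            circular = False
        elif "circular" in tokens:
            circular = True
        species = " ".join(rec.description.split()[1:3]) if len(
            rec.description.split()) > 1 else ""
        genomes.append(MitoGenome(
            id=rec.id, sequence=str(rec.seq), species=species, circular=circular,
        ))
    return genomes


def write_genome_fasta(genomes: list[MitoGenome], path: str | Path,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            topo = "circular" if g.circular else "linear"
            header = f">{g.id} {topo}"
            if g.species:
                header += f" {g.species}"
            fh.write(header + "\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i:i + width] + "\n")


def _parse_pct(value: str) -> float:
    return float(value)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Parse one annotation table (single genome_id per file)."""
    lines = Path(path).read_text().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise ValueError(f"empty feature table {path}")
    header = rows[0].split("\t")
    missing = [c for c in _TABLE_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {missing}")
    idx = {c: header.index(c) for c in _TABLE_COLUMNS}

    genome_id = None
    features = []
    for lineno, row in enumerate(rows[1:], start=2):
        f = row.split("\t")
        name = f[idx["name"]].strip()
        strand = f[idx["strand"]].strip() or "H"
        if "[C]" in name:            # legacy L-strand marker
            name = name.replace("[C]", "").strip()
            strand = "L"
        try:
            start = int(f[idx["start"]])
            end = int(f[idx["end"]])
            length = int(f[idx["declared_length"]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate: {exc}")
        if start < 1 or end < 1:
            raise ValueError(
                f"{path}:{lineno}: coordinates are 1-based, got {start}..{end}")
        gid = f[idx["genome_id"]].strip()
        if genome_id is None:
            genome_id = gid
        elif gid != genome_id:
            raise ValueError(
                f"{path}:{lineno}: mixed genome ids {genome_id!r}/{gid!r}")
        pct = {b: _parse_pct(f[idx["pct" + b]]) for b in "ACGT"}
        features.append(Feature(
            kind=f[idx["kind"]].strip(),
            name=name,
            strand=strand,
            start=start,
            end=end,
            declared_length=length,
            start_codon=f[idx["start_codon"]].strip().upper(),
            stop_codon=f[idx["stop_codon"]].strip().upper(),
            pct=pct,
        ))
    return FeatureTable(genome_id=genome_id, features=features)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialize a table in the canonical dialect (read/write round-trips)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in table:
            pct = f.pct or {b: 0.0 for b in "ACGT"}
            fh.write("\t".join([
                table.genome_id, f.kind, f.name, f.strand,
                str(f.start), str(f.end), str(f.declared_length),
                f.start_codon, f.stop_codon,
                f"{pct['A']:.1f}", f"{pct['C']:.1f}",
                f"{pct['G']:.1f}", f"{pct['T']:.1f}",
            ]) + "\n")


def read_read_stats(path: str | Path) -> list[ReadStats]:
    lines = Path(path).read_text().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise ValueError(f"empty read-stats table {path}")
    header = rows[0].split("\t")
    cols = ["genome_id", "total_reads", "mapped_reads", "total_nt",
            "mapped_nt", "genome_length"]
    missing = [c for c in cols if c not in header]
    if missing:
        raise ValueError(f"read-stats table {path} missing columns: {missing}")
    idx = {c: header.index(c) for c in cols}
    out = []
    for row in rows[1:]:
        f = row.split("\t")
        out.append(ReadStats(
            genome_id=f[idx["genome_id"]].strip(),
            total_reads=int(f[idx["total_reads"]]),
            mapped_reads=int(f[idx["mapped_reads"]]),
            total_nt=int(f[idx["total_nt"]]),
            mapped_nt=int(f[idx["mapped_nt"]]),
            genome_length=int(f[idx["genome_length"]]),
        ))
    return out


def write_violations(violations: list[Violation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("code\tseverity\tfeature\tmessage\n")
        for v in violations:
            fh.write(f"{v.code}\t{v.severity}\t{v.feature}\t{v.message}\n")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{label: aligned sequence}``.

    All sequences must have equal aligned length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    aln = {rec.id: str(rec.seq).upper() for rec in records}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment {path} has unequal sequence lengths {lengths}")
    return aln


def _data_path(name: str):
    return importlib.resources.files("mitocomp").joinpath("data", name)


def load_published_feature_table(species: str) -> FeatureTable:
    """Load the shipped annotation table for XL, ST, XB or XV."""
    if species not in PUBLISHED_SPECIES:
        raise KeyError(f"species must be one of {PUBLISHED_SPECIES}")
    with importlib.resources.as_file(_data_path(f"{species}_features.tsv")) as p:
        return read_feature_table(p)


def load_published_read_stats() -> dict[str, ReadStats]:
    """Load the shipped sequencing-run statistics (XB and XV)."""
    with importlib.resources.as_file(_data_path("read_stats.tsv")) as p:
        return {s.genome_id: s for s in read_read_stats(p)}
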