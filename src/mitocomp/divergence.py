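"""Sliding-window nucleotide divergence with Jukes-Cantor correction.

Divergence between aligned sequences is measured as K(JC), the expected
number of substitutions per site under the Jukes-Cantor model::

    K = -(3/4) * ln(1 - (4/3) * p)

where ``p`` is the proportion of differing sites among comparable sites
(pairwise deletion: columns with a gap or ambiguity code in either sequence
are excluded).  ``p >= 3/4`` is beyond saturation and yields an undefined
value rather than an exception.  Window coordinates are alignment
coordinates, 1-based inclusive, as produced by sliding-window tools such as
DnaSP.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .model import MitoGenome, reverse_complement

__all__ = [
    "WindowSpec",
    "DivergenceProfile",
    "p_distance",
    "jc_divergence",
    "sliding_window_profile",
    "region_capture",
    "motif_similarity_scan",
]

_ACGT = frozenset(b"ACGT")


@dataclass
class WindowSpec:
    """Sliding-window geometry: width, step and the sparse-window guard."""

    window: int = 300
    step: int = 10
    min_valid_sites: int | None = None    # default: window // 2

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError(
                f"require window >= step >= 1, got window={self.window} "
                f"step={self.step}")
        if self.min_valid_sites is None:
            self.min_valid_sites = self.window // 2
        if self.min_valid_sites > self.window:
            raise ValueError("min_valid_sites exceeds window size")


@dataclass
class DivergenceProfile:
    """Per-window K(JC) values over an alignment.

    ``k`` holds ``nan`` for undefined windows (sparse, saturated or masked).
    Midpoints are 1-based alignment coordinates, strictly increasing by the
    window step.
    """

    label: str
    midpoints: np.ndarray
    k: np.ndarray
    valid_sites: np.ndarray
    n_pairs: int
    spec: WindowSpec = field(default_factory=WindowSpec)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# alignment coordinates, 1-based inclusive midpoints\n")
            fh.write("midpoint\tK_JC\tvalid_sites\tn_pairs\n")
            for m, k, v in zip(self.midpoints, self.k, self.valid_sites):
                kstr = "NA" if math.isnan(k) else f"{k:.6f}"
                fh.write(f"{m}\t{kstr}\t{v}\t{self.n_pairs}\n")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _valid_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok_a = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
    ok_b = (b == ord("A")) | (b == ord("C")) | (b == ord("G")) | (b == ord("T"))
    return ok_a & ok_b


def p_distance(a: str, b: str) -> dict:
    """Uncorrected pairwise distance with pairwise deletion.

    Sites carrying a gap or ambiguity code in either sequence are excluded;
    ``p = mismatches / valid_sites``.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    xa, xb = _encode(a), _encode(b)
    valid = _valid_mask(xa, xb)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid (ungapped, unambiguous) sites to compare")
    mism = int((valid & (xa != xb)).sum())
    return {"p": mism / n, "valid_sites": n, "mismatches": mism}


def jc_divergence(p: float) -> float:
    """Jukes-Cantor corrected divergence; ``nan`` at/beyond saturation."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _window_starts(aln_len: int, spec: WindowSpec) -> tuple[np.ndarray, int]:
    """0-based window start offsets and the effective window width."""
    if aln_len < spec.window:
        warnings.warn(
            f"alignment ({aln_len} nt) shorter than window ({spec.window} nt); "
            "emitting a single truncated window")
        return np.array([0]), aln_len
    n = (aln_len - spec.window) // spec.step + 1
    return np.arange(n) * spec.step, spec.window


def sliding_window_profile(
    alignment: dict[str, str],
    spec: WindowSpec | None = None,
    pair: tuple[str, str] | None = None,
    mask: list[tuple[int, int]] | None = None,
) -> DivergenceProfile:
    """K(JC) in sliding windows over an alignment.

    With ``pair`` the profile is for that taxon pair; otherwise it is the
    unweighted arithmetic mean of K over all unordered pairs.  A window is
    undefined (``nan``) when any contributing pair has fewer than
    ``min_valid_sites`` comparable sites or is saturated, or when the window
    intersects a masked alignment interval (``mask``: 1-based inclusive
    intervals, e.g. an unalignable control region).
    """
    spec = spec or WindowSpec()
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two aligned sequences")
    aln_len = len(next(iter(alignment.values())))
    if any(len(s) != aln_len for s in alignment.values()):
        raise ValueError("aligned sequences have unequal lengths")

    if pair is not None:
        pairs = [tuple(pair)]
        label = f"{pair[0]} vs {pair[1]}"
    else:
        pairs = list(combinations(labels, 2))
        label = f"all-pairs mean ({len(labels)} taxa)"

    starts, width = _window_starts(aln_len, spec)
    n_win = len(starts)
    ends = np.minimum(starts + width, aln_len)

    # per-pair cumulative valid/mismatch counts -> O(1) per window
    per_pair_valid = np.empty((len(pairs), n_win), dtype=int)
    per_pair_mism = np.empty((len(pairs), n_win), dtype=int)
    for i, (la, lb) in enumerate(pairs):
        xa, xb = _encode(alignment[la]), _encode(alignment[lb])
        valid = _valid_mask(xa, xb)
        mism = valid & (xa != xb)
        cv = np.concatenate([[0], np.cumsum(valid)])
        cm = np.concatenate([[0], np.cumsum(mism)])
        per_pair_valid[i] = cv[ends] - cv[starts]
        per_pair_mism[i] = cm[ends] - cm[starts]

    k = np.full(n_win, np.nan)
    valid_sites = per_pair_valid.min(axis=0)
    min_sites = min(spec.min_valid_sites, width)
    for w in range(n_win):
        if valid_sites[w] < max(min_sites, 1):
            continue
        ks = []
        ok = True
        for i in range(len(pairs)):
            p = per_pair_mism[i, w] / per_pair_valid[i, w]
            kv = jc_divergence(p)
            if math.isnan(kv):
                ok = False
                break
            ks.append(kv)
        if ok:
            k[w] = float(np.mean(ks))

    midpoints = starts + (width + 1) // 2      # 1-based midpoint
    if mask:
        for (ms, me) in mask:
            hit = (starts + 1 <= me) & (ends >= ms)
            k[hit] = np.nan
    return DivergenceProfile(
        label=label,
        midpoints=midpoints.astype(int),
        k=k,
        valid_sites=valid_sites,
        n_pairs=len(pairs),
        spec=spec,
    )


def region_capture(profile: DivergenceProfile,
                   regions: list[tuple[str, int, int]]) -> list[dict]:
    """Mean window K inside labelled alignment intervals, ranked descending.

    ``regions`` are ``(label, start, end)`` in 1-based inclusive alignment
    coordinates; a window contributes when its midpoint falls inside the
    interval and its K is defined.
    """
    out = []
    for (label, start, end) in regions:
        inside = (profile.midpoints >= start) & (profile.midpoints <= end)
        vals = profile.k[inside]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(
                f"region {label!r} ({start}..{end}) contains no defined window")
        out.append({"region": label, "start": start, "end": end,
                    "mean_K": float(vals.mean()), "n_windows": int(vals.size)})
    out.sort(key=lambda r: -r["mean_K"])
    for rank, rec in enumerate(out, start=1):
        rec["rank"] = rank
    return out


def motif_similarity_scan(
    genome: MitoGenome,
    motif: str,
    identity_threshold: float = 0.75,
    strand: str = "H",
) -> list[dict]:
    """Ungapped scan of a motif against every genome offset.

    Circular genomes are scanned across the origin.  Identity is
    matches/motif-length; hits at or above ``identity_threshold`` are
    returned sorted by descending identity (ties by position).  With
    ``strand="both"`` the reverse complement of the motif is scanned too.
    """
    motif = motif.upper()
    m = len(motif)
    if m == 0:
        raise ValueError("empty motif")
    if m > genome.length:
        raise ValueError("motif longer than genome")

    seq = genome.sequence
    ext = seq + seq[:m - 1] if genome.circular else seq
    n_off = len(ext) - m + 1
    ext_arr = _encode(ext)

    def scan(query: str, strand_label: str) -> list[dict]:
        q = _encode(query)
        matches = np.zeros(n_off, dtype=int)
        for j in range(m):
            matches += ext_arr[j:j + n_off] == q[j]
        ident = matches / m
        hits = np.nonzero(ident >= identity_threshold)[0]
        return [{"position": int(i) + 1, "strand": strand_label,
                 "pct_identity": float(100.0 * ident[i])} for i in hits]

    results = scan(motif, "H")
    if strand == "both":
        results += scan(reverse_complement(motif), "L")
    elif strand != "H":
        raise ValueError("strand must be 'H' or 'both'")
    results.sort(key=lambda h: (-h["pct_identity"], h["position"]))
    return results
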