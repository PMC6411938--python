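"""Length distributions and first-nucleotide composition.

The length histogram is normalized to reads-per-million miRNA-proxy reads,
where the miRNA proxy is the library's total 21-23 nt read count — the
convention that makes libraries of different depths comparable.  The first
nucleotide is taken from the sequenced read (its 5'-most base), never from
the reference strand context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .sequence_io import CollapsedRead

RPM_SCALE = 1_000_000
MIRNA_BOUNDS = (21, 23)


@dataclass
class LengthDistribution:
    table: pd.DataFrame  # columns: length, raw, normalized
    mirna_proxy_reads: int
    normalized: bool


@dataclass
class NucleotideComposition:
    fractions: dict[str, float]  # keys A, C, G, U
    total: int
    n_excluded: int  # N-started reads, excluded from the denominator


def mirna_proxy_count(
    reads: Sequence[CollapsedRead], bounds: tuple[int, int] = MIRNA_BOUNDS
) -> int:
    """Total count of reads in the miRNA length window (21-23 nt inclusive)."""
    lo, hi = bounds
    return sum(r.count for r in reads if lo <= len(r) <= hi)


def length_distribution(
    reads: Sequence[CollapsedRead],
    normalize: bool = True,
    mirna_bounds: tuple[int, int] = MIRNA_BOUNDS,
    length_range: tuple[int, int] = (18, 48),
) -> LengthDistribution:
    """Count-weighted read-length histogram, optionally in RPM-miRNA units.

    When ``normalize`` is set each bin is scaled by 1e6 / (total 21-23 nt
    reads); requesting normalization on a library with zero miRNA-proxy
    reads is an error, since the scale would be undefined.
    """
    counts: dict[int, int] = {}
    for r in reads:
        counts[len(r)] = counts.get(len(r), 0) + r.count
    proxy = mirna_proxy_count(reads, mirna_bounds)
    if normalize and proxy == 0:
        raise ValueError(
            "miRNA normalization requested but the library has no "
            f"{mirna_bounds[0]}-{mirna_bounds[1]} nt reads"
        )
    lo, hi = length_range
    lengths = sorted(set(range(lo, hi + 1)) | set(counts))
    rows = []
    for length in lengths:
        raw = counts.get(length, 0)
        norm = raw * (RPM_SCALE / proxy) if normalize else float(raw)
        rows.append((length, raw, norm))
    table = pd.DataFrame(rows, columns=["length", "raw", "normalized"])
    return LengthDistribution(table=table, mirna_proxy_reads=proxy, normalized=normalize)


def first_nt_composition(reads: Sequence[CollapsedRead]) -> NucleotideComposition:
    """Count-weighted base frequencies at read position 1 (5'-most base).

    T is reported as U (the RNA base actually sequenced).  Reads starting
    with N are excluded from the denominator and counted separately.
    """
    tallies = {"A": 0, "C": 0, "G": 0, "U": 0}
    excluded = 0
    for r in reads:
        base = r.sequence[0]
        if base == "T":
            base = "U"
        if base in tallies:
            tallies[base] += r.count
        else:
            excluded += r.count
    total = sum(tallies.values())
    if total == 0:
        fractions = {b: 0.0 for b in tallies}
    else:
        fractions = {b: n / total for b, n in tallies.items()}
    return NucleotideComposition(fractions=fractions, total=total, n_excluded=excluded)
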