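"""Ungapped read-to-reference alignment with a bounded mismatch allowance.

The production aligner is seed-and-extend over an exact 12-mer index; for a
read of length >= 24 and at most one substitution, one of the two disjoint
leading 12-mers is mismatch-free (pigeonhole), so the candidate set is
complete.  Shorter reads fall back to the exhaustive scan.  Correctness is
defined solely by equivalence with :func:`brute_force_align`, the vectorized
all-positions Hamming scan used as the test oracle.

Two mismatch regimes are used by the pipeline: annotation allows one
substitution; end-distance analysis demands perfect matches.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sequence_io import CollapsedRead, ReferenceSet, revcomp

_SEED_K = 12


@dataclass(frozen=True)
class Alignment:
    """An ungapped placement of a read on a reference (0-based half-open).

    For strand '-', the reverse complement of the read matches
    ``reference[start:end]`` with the stated mismatch count.
    """

    read_id: str
    reference_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def end_coord(self, end: str) -> int:
        """Half-open-style bound of the 5' or 3' side, oriented by strand."""
        if end == "5p":
            return self.start if self.strand == "+" else self.end
        if end == "3p":
            return self.end if self.strand == "+" else self.start
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")


@dataclass
class AlignConfig:
    max_mismatch: int = 1
    strands: str = "both"  # both | plus_only
    report: str = "all"  # all | any

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.strands not in ("both", "plus_only"):
            raise ValueError("strands must be 'both' or 'plus_only'")
        if self.report not in ("all", "any"):
            raise ValueError("report must be 'all' or 'any'")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ReferenceIndex:
    """Exact 12-mer positional index over one reference set."""

    def __init__(self, reference_set: ReferenceSet, k: int = _SEED_K):
        self.k = k
        self.ids = [rid for rid, _ in reference_set.records]
        self.seqs = [seq for _, seq in reference_set.records]
        self.arrays = [_encode(seq) for seq in self.seqs]
        self.kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ri, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                self.kmers[seq[pos : pos + k]].append((ri, pos))


def _strand_list(config: AlignConfig) -> tuple[str, ...]:
    return ("+", "-") if config.strands == "both" else ("+",)


def _scan_all_positions(
    qarr: np.ndarray, ref_arr: np.ndarray, max_mismatch: int
) -> np.ndarray:
    """Start positions where the query matches with <= max_mismatch substitutions."""
    L = len(qarr)
    if L > len(ref_arr):
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(ref_arr, L)
    mm = np.count_nonzero(windows != qarr, axis=1)
    return np.nonzero(mm <= max_mismatch)[0]


def align(
    reads: Sequence[CollapsedRead],
    reference_set: ReferenceSet | ReferenceIndex,
    config: AlignConfig,
) -> list[Alignment]:
    """Align reads to a reference set; substitutions only, no indels.

    N-containing reads are dropped.  With ``report='all'`` every placement
    with at most ``max_mismatch`` substitutions is returned; with ``'any'``
    the first placement in the deterministic (reference id, start, strand)
    order.  Hits are grouped per read in input order.
    """
    index = (
        reference_set
        if isinstance(reference_set, ReferenceIndex)
        else ReferenceIndex(reference_set)
    )
    k = index.k
    out: list[Alignment] = []
    for read in reads:
        seq = read.sequence
        if "N" in seq:
            continue
        hits: set[tuple[int, int, str]] = set()
        for strand in _strand_list(config):
            q = seq if strand == "+" else revcomp(seq)
            qarr = _encode(q)
            L = len(q)
            needed = k * (config.max_mismatch + 1)
            if L < needed:
                for ri, ref_arr in enumerate(index.arrays):
                    for s in _scan_all_positions(qarr, ref_arr, config.max_mismatch):
                        hits.add((ri, int(s), strand))
                continue
            candidates: set[tuple[int, int]] = set()
            offsets = (0,) if config.max_mismatch == 0 else (0, k)
            for off in offsets:
                for ri, pos in index.kmers.get(q[off : off + k], ()):
                    candidates.add((ri, pos - off))
            for ri, s in candidates:
                ref_arr = index.arrays[ri]
                if s < 0 or s + L > len(ref_arr):
                    continue
                mm = int(np.count_nonzero(ref_arr[s : s + L] != qarr))
                if mm <= config.max_mismatch:
                    hits.add((ri, s, strand))
        read_hits = [
            Alignment(
                read_id=read.id,
                reference_id=index.ids[ri],
                start=s,
                end=s + len(seq),
                strand=strand,
                mismatches=int(
                    np.count_nonzero(
                        index.arrays[ri][s : s + len(seq)]
                        != _encode(seq if strand == "+" else revcomp(seq))
                    )
                ),
                count=read.count,
            )
            for ri, s, strand in hits
        ]
        read_hits.sort(key=lambda a: (a.reference_id, a.start, a.strand))
        if config.report == "any" and read_hits:
            read_hits = read_hits[:1]
        out.extend(read_hits)
    return out


def brute_force_align(
    reads: Sequence[CollapsedRead],
    reference_set: ReferenceSet | ReferenceIndex,
    config: AlignConfig,
) -> list[Alignment]:
    """Exhaustive all-positions Hamming scan with the same contract as align.

    Test oracle: every (reference, start, strand) placement is examined.
    """
    index = (
        reference_set
        if isinstance(reference_set, ReferenceIndex)
        else ReferenceIndex(reference_set)
    )
    out: list[Alignment] = []
    for read in reads:
        seq = read.sequence
        if "N" in seq:
            continue
        read_hits: list[Alignment] = []
        for strand in _strand_list(config):
            q = seq if strand == "+" else revcomp(seq)
            qarr = _encode(q)
            for ri, ref_arr in enumerate(index.arrays):
                for s in _scan_all_positions(qarr, ref_arr, config.max_mismatch):
                    s = int(s)
                    mm = int(np.count_nonzero(ref_arr[s : s + len(q)] != qarr))
                    read_hits.append(
                        Alignment(
                            read_id=read.id,
                            reference_id=index.ids[ri],
                            start=s,
                            end=s + len(q),
                            strand=strand,
                            mismatches=mm,
                            count=read.count,
                        )
                    )
        read_hits.sort(key=lambda a: (a.reference_id, a.start, a.strand))
        if config.report == "any" and read_hits:
            read_hits = read_hits[:1]
        out.extend(read_hits)
    return out
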