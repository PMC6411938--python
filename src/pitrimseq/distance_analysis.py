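"""5'-5' and 3'-3' end-distance analysis against reference piRNAs.

The diagnostic at the heart of the pipeline: the most abundant uniquely
mapped wild-type piRNAs serve as positional anchors (their 5' or 3' ends
define offset 0), and a query library's read ends are histogrammed at
signed offsets within a fixed window around those anchors.  A 5'-5' peak at
0 combined with 3'-3' mass strictly downstream diagnoses reads that share
mature 5' ends but carry untrimmed 3' ends — the signature of a 3'-trimming
defect.

Offsets are signed along each reference piRNA's own 5'->3' orientation
(positive = downstream), so a 3' extension is positive on either genomic
strand.  Only perfect-match placements participate.  Frequencies are
normalized over in-window events, so profiles from libraries of different
depths are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignConfig, Alignment, ReferenceIndex, align
from .sequence_io import CollapsedRead, ReferenceSet


@dataclass(frozen=True)
class ReferencePiRNA:
    """A top-ranked, uniquely mapped wild-type piRNA used as a position anchor.

    anchor5/anchor3 are half-open-style bounds oriented by strand (plus:
    anchor5 = start, anchor3 = end; minus: anchor5 = end, anchor3 = start).
    """

    sequence: str
    cluster_id: str
    strand: str
    anchor5: int
    anchor3: int
    count: int
    rank: int


@dataclass
class DistanceProfile:
    """Frequency of query end positions at offsets -w..+w around anchors."""

    end: str  # 5p | 3p
    offsets: np.ndarray
    frequencies: np.ndarray
    events: np.ndarray  # count-weighted in-window events per offset
    total: float

    def frequency_at(self, offset: int) -> float:
        w = (len(self.offsets) - 1) // 2
        return float(self.frequencies[offset + w])

    def mass(self, lo: int, hi: int) -> float:
        """Summed frequency over offsets lo..hi inclusive."""
        w = (len(self.offsets) - 1) // 2
        lo_i = max(lo + w, 0)
        hi_i = min(hi + w, len(self.offsets) - 1)
        return float(self.frequencies[lo_i : hi_i + 1].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "frequency": self.frequencies, "events": self.events}
        )


@dataclass
class ClusterPileup:
    cluster_id: str
    region: tuple[int, int]
    track_a: list[Alignment] = field(default_factory=list)  # short class (24-30)
    track_b: list[Alignment] = field(default_factory=list)  # long class (31-48)
    shared_5p_pairs: int = 0  # distinct (5' position, strand) present in both


PERFECT = AlignConfig(max_mismatch=0, strands="both", report="all")


def select_reference_pirnas(
    wt_reads: Sequence[CollapsedRead],
    cluster_references: ReferenceSet | ReferenceIndex,
    n: int = 10_000,
    unique_only: bool = True,
) -> list[ReferencePiRNA]:
    """Select the top-N distinctively mapped wild-type piRNAs as anchors.

    "Distinctively mapped" is read as uniquely mapped: a distinct sequence
    with exactly one perfect-match placement across the piRNA cluster
    references (both strands) — the only reading that yields unambiguous
    position-0 anchors.  With ``unique_only=False`` every distinct mapped
    sequence qualifies and its first placement (deterministic order) is the
    anchor.  Ties broken by (count desc, sequence lexicographic).
    """
    hits_by_read: dict[str, list[Alignment]] = {}
    for a in align(wt_reads, cluster_references, PERFECT):
        hits_by_read.setdefault(a.read_id, []).append(a)
    reads_by_id = {r.id: r for r in wt_reads}

    candidates: list[tuple[CollapsedRead, Alignment]] = []
    for rid, hits in hits_by_read.items():
        if unique_only and len(hits) != 1:
            continue
        candidates.append((reads_by_id[rid], hits[0]))
    if not candidates:
        raise ValueError("no qualifying uniquely mapped wild-type piRNAs found")
    candidates.sort(key=lambda ra: (-ra[0].count, ra[0].sequence))
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} qualifying piRNAs available (requested {n})",
            stacklevel=2,
        )
    selected = candidates[:n]
    return [
        ReferencePiRNA(
            sequence=read.sequence,
            cluster_id=aln.reference_id,
            strand=aln.strand,
            anchor5=aln.end_coord("5p"),
            anchor3=aln.end_coord("3p"),
            count=read.count,
            rank=rank + 1,
        )
        for rank, (read, aln) in enumerate(selected)
    ]


def distance_profile(
    references: Sequence[ReferencePiRNA],
    query_reads: Sequence[CollapsedRead] | None,
    cluster_references: ReferenceSet | ReferenceIndex | None,
    end: str = "5p",
    half_window: int = 30,
    multimap_weight: str = "full",
    query_alignments: Sequence[Alignment] | None = None,
) -> DistanceProfile:
    """End-distance frequency profile of a query library around anchors.

    Each perfect-match query placement on the same cluster and strand as a
    reference contributes its count at the signed offset of its 5' (or 3')
    end from the reference's matching anchor, for EVERY reference whose
    anchor lies within ``half_window``; frequencies are then normalized over
    all in-window events.  ``multimap_weight='fractional'`` down-weights a
    read's placements by 1/(number of placements) instead of full count.

    Pre-computed perfect-match ``query_alignments`` may be passed instead of
    ``query_reads`` + ``cluster_references``.
    """
    if end not in ("5p", "3p"):
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")
    if not references:
        raise ValueError("empty reference piRNA list")
    if query_alignments is None:
        if query_reads is None or cluster_references is None:
            raise ValueError("need query_reads and cluster_references, or query_alignments")
        query_alignments = align(query_reads, cluster_references, PERFECT)

    anchors: dict[tuple[str, str], np.ndarray] = {}
    for key in {(r.cluster_id, r.strand) for r in references}:
        vals = [
            (r.anchor5 if end == "5p" else r.anchor3)
            for r in references
            if (r.cluster_id, r.strand) == key
        ]
        anchors[key] = np.sort(np.asarray(vals, dtype=np.int64))

    placements_per_read: dict[str, int] = {}
    if multimap_weight == "fractional":
        for a in query_alignments:
            placements_per_read[a.read_id] = placements_per_read.get(a.read_id, 0) + 1
    elif multimap_weight != "full":
        raise ValueError("multimap_weight must be 'full' or 'fractional'")

    w = half_window
    events = np.zeros(2 * w + 1, dtype=float)
    for a in query_alignments:
        arr = anchors.get((a.reference_id, a.strand))
        if arr is None:
            continue
        q = a.end_coord(end)
        lo = np.searchsorted(arr, q - w, side="left")
        hi = np.searchsorted(arr, q + w, side="right")
        if lo == hi:
            continue
        weight = a.count
        if multimap_weight == "fractional":
            weight = a.count / placements_per_read[a.read_id]
        sign = 1 if a.strand == "+" else -1
        for anchor in arr[lo:hi]:
            events[(q - int(anchor)) * sign + w] += weight

    total = float(events.sum())
    if total > 0:
        freqs = events / total
    else:
        warnings.warn("zero in-window end events; returning an all-zero profile",
                      stacklevel=2)
        freqs = np.zeros_like(events)
    return DistanceProfile(
        end=end,
        offsets=np.arange(-w, w + 1),
        frequencies=freqs,
        events=events,
        total=total,
    )


def cluster_pileup(
    alignments_a: Sequence[Alignment],
    alignments_b: Sequence[Alignment],
    cluster_id: str,
    region: tuple[int, int],
    known_clusters: set[str] | None = None,
    class_a: tuple[int, int] = (24, 30),
    class_b: tuple[int, int] = (31, 48),
) -> ClusterPileup:
    """Per-cluster read-track view: mature-length vs extended-length reads.

    Track A takes ``alignments_a`` in the 24-30 nt class, track B takes
    ``alignments_b`` in the 31-48 nt class; reads must lie entirely within
    ``region`` (0-based half-open).  Shared-5' pairs — a (5' position,
    strand) anchor occupied in both tracks — are counted: these are the
    mature/intermediate pairs the view exists to expose.
    """
    if known_clusters is not None and cluster_id not in known_clusters:
        raise ValueError(f"unknown cluster id {cluster_id!r}")
    lo, hi = region

    def pick(alns: Sequence[Alignment], length_class: tuple[int, int]) -> list[Alignment]:
        cmin, cmax = length_class
        out = [
            a
            for a in alns
            if a.reference_id == cluster_id
            and a.start >= lo
            and a.end <= hi
            and cmin <= a.length <= cmax
        ]
        out.sort(key=lambda a: (a.start, a.end, a.strand))
        return out

    track_a = pick(alignments_a, class_a)
    track_b = pick(alignments_b, class_b)
    ends_a = {(a.end_coord("5p"), a.strand) for a in track_a}
    ends_b = {(a.end_coord("5p"), a.strand) for a in track_b}
    return ClusterPileup(
        cluster_id=cluster_id,
        region=region,
        track_a=track_a,
        track_b=track_b,
        shared_5p_pairs=len(ends_a & ends_b),
    )
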