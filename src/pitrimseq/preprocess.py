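"""3'-adapter clipping and the 24-48 nt length filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import CollapsedRead


@dataclass
class ClipConfig:
    adapter: str
    min_overlap: int = 6
    max_mismatch_per_overlap: int = 0
    min_len: int = 24
    max_len: int = 48

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if len(self.adapter) < self.min_overlap:
            raise ValueError(
                f"adapter ({len(self.adapter)} nt) shorter than min_overlap "
                f"({self.min_overlap})"
            )
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def _matches(a: str, b: str, max_mismatch: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def clip_adapter(sequence: str, config: ClipConfig) -> tuple[str, str]:
    """Remove 3'-adapter read-through; return ``(clipped, status)``.

    The leftmost position where an adapter prefix of length >= min_overlap
    matches the read (the full adapter where it fits, a prefix of the adapter
    against the read's 3' suffix otherwise) wins; everything 5' of it is
    kept.  Status is one of ``clipped``, ``no_adapter``, ``empty_after_clip``.
    Reads with no adapter hit are returned unchanged: they may be genuine
    near-full-length intermediates whose adapter fell off the read end.
    """
    adapter = config.adapter
    n, m = len(sequence), len(adapter)
    for i in range(0, n - config.min_overlap + 1):
        span = min(m, n - i)
        if _matches(sequence[i : i + span], adapter[:span], config.max_mismatch_per_overlap):
            if i == 0:
                return "", "empty_after_clip"
            return sequence[:i], "clipped"
    return sequence, "no_adapter"


def filter_by_length(
    reads: Sequence[CollapsedRead], min_len: int = 24, max_len: int = 48
) -> tuple[list[CollapsedRead], pd.DataFrame]:
    """Retain reads with min_len <= length <= max_len (both ends inclusive).

    The report tallies count-weighted retained/discarded reads per length;
    retained + discarded always equals the input total.
    """
    retained: list[CollapsedRead] = []
    rows: dict[int, list[int]] = {}
    for r in reads:
        keep = min_len <= len(r) <= max_len
        bucket = rows.setdefault(len(r), [0, 0])
        bucket[0 if keep else 1] += r.count
        if keep:
            retained.append(r)
    report = pd.DataFrame(
        [(length, kept, dropped) for length, (kept, dropped) in sorted(rows.items())],
        columns=["length", "retained", "discarded"],
    )
    return retained, report


def clip_reads(
    raw_reads: Iterable[tuple[str, str]], config: ClipConfig
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Clip every raw read; drop reads that are empty after clipping.

    Returns the clipped read stream and a status tally.  ``no_adapter``
    reads are kept (and counted) per the stated policy.
    """
    kept: list[tuple[str, str]] = []
    tally = {"clipped": 0, "no_adapter": 0, "empty_after_clip": 0}
    for rid, seq in raw_reads:
        clipped, status = clip_adapter(seq, config)
        tally[status] += 1
        if status != "empty_after_clip":
            kept.append((rid, clipped))
    return kept, tally
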