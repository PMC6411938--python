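"""Hierarchical genomic annotation of small-RNA reads.

Each read is assigned to the highest-priority reference set in which it has
at least one alignment (sequential filtering: once assigned, a read is never
tested against lower-priority sets).  Reads hitting none of the five sets
are classified as "other".  Percentages are count-weighted so each raw read
counts once, reproducing per-read tallies on collapsed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .alignment import AlignConfig, align
from .sequence_io import CollapsedRead, ReferenceSet

OTHER = "other"


@dataclass
class AnnotationResult:
    assignments: dict[str, str]  # read id -> category
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    total_count: int = 0


def annotate_hierarchical(
    reads: Sequence[CollapsedRead],
    reference_sets: Sequence[ReferenceSet],
    config: AlignConfig | None = None,
) -> AnnotationResult:
    """Assign each read to exactly one category by the fixed priority order.

    ``reference_sets`` must carry distinct priorities; they are processed in
    ascending priority.  Alignment existence (report='any', both strands,
    <= max_mismatch substitutions anywhere in the set) suffices for
    assignment — no coverage threshold.
    """
    if config is None:
        config = AlignConfig(max_mismatch=1, strands="both", report="any")
    priorities = [rs.priority for rs in reference_sets]
    if len(set(priorities)) != len(priorities):
        raise ValueError(f"duplicate priorities in reference sets: {priorities}")
    ordered = sorted(reference_sets, key=lambda rs: rs.priority)

    existence = AlignConfig(
        max_mismatch=config.max_mismatch, strands=config.strands, report="any"
    )
    assignments: dict[str, str] = {}
    remaining = list(reads)
    for refset in ordered:
        if not remaining:
            break
        hit_ids = {a.read_id for a in align(remaining, refset, existence)}
        next_remaining = []
        for r in remaining:
            if r.id in hit_ids:
                assignments[r.id] = refset.category
            else:
                next_remaining.append(r)
        remaining = next_remaining
    for r in remaining:
        assignments[r.id] = OTHER

    result = AnnotationResult(assignments=assignments)
    result.summary = annotation_report(result, reads, [rs.category for rs in ordered])
    result.total_count = sum(r.count for r in reads)
    return result


def annotation_report(
    result: AnnotationResult,
    reads: Sequence[CollapsedRead],
    category_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count-weighted reads and percentage per category, over all input reads."""
    counts: dict[str, int] = {}
    for r in reads:
        cat = result.assignments[r.id]
        counts[cat] = counts.get(cat, 0) + r.count
    total = sum(counts.values())
    if total == 0:
        raise ValueError("annotation report requires a non-empty read set")
    if category_order is None:
        category_order = sorted(c for c in counts if c != OTHER)
    rows = []
    for cat in list(category_order) + [OTHER]:
        n = counts.get(cat, 0)
        rows.append((cat, n, 100.0 * n / total))
    return pd.DataFrame(rows, columns=["category", "reads", "percent"])
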