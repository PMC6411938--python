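"""Reading and writing the formats the pipeline touches.

All coordinates are 0-based half-open.  BED6 is the only coordinate-bearing
output format.  FASTA/FASTQ parsing is delegated to Biopython; the collapsed
FASTA dialect (``>{id}_x{count}``, a common smallRNA convention) and BED6 are
small line formats handled directly.  All readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

CATEGORIES = ("piRNA_cluster", "coding_RNA", "noncoding_RNA", "repeats", "intron")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct small-RNA sequence with its raw-read multiplicity.

    Collapsing is lossless: the sum of ``count`` over all collapsed reads
    equals the raw read total, so every count-weighted statistic downstream
    equals the per-read computation.
    """

    id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.count < 1:
            raise ValueError(f"read {self.id!r}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """An ordered, category-labeled collection of reference sequences.

    ``priority`` is the rank in the hierarchical annotation order; the five
    canonical categories carry priorities 1..5 in the order of CATEGORIES.
    """

    category: str
    records: list[tuple[str, str]] = field(default_factory=list)
    priority: int = 0

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open a file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` from a 4-line FASTQ in file order.

    Raises ValueError naming the record index on a truncated record or a
    sequence/quality length mismatch.
    """
    with xopen(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ at record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ at record {index} ({title.split()[0]}): "
                    f"sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield title.split()[0], seq.upper()
            index += 1


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as Phred+33 FASTQ with constant 'I' quality."""
    with xopen(path, "wt") as out:
        for rid, seq in reads:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA into ``[(id, sequence), ...]``."""
    with xopen(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with xopen(path, "wt") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Collapsing


def collapse_reads(raw_reads: Iterable[tuple[str, str]]) -> list[CollapsedRead]:
    """Collapse raw reads to one entry per distinct sequence.

    Counts conserve the raw total.  Output is sorted by count descending then
    sequence lexicographic, and ids are assigned ``seq{rank}`` in that order.
    """
    counts: dict[str, int] = {}
    for _rid, seq in raw_reads:
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(id=f"seq{i + 1}", sequence=seq, count=n)
        for i, (seq, n) in enumerate(ordered)
    ]


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads in the ``>{id}_x{count}`` smallRNA dialect."""
    with xopen(path, "wt") as out:
        for r in reads:
            out.write(f">{r.id}_x{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read the ``>{id}_x{count}`` dialect back into CollapsedRead records."""
    out = []
    for rid, seq in read_fasta(path):
        base, _, suffix = rid.rpartition("_x")
        if not base or not suffix.isdigit():
            raise ValueError(f"header {rid!r} lacks the _x<count> suffix")
        out.append(CollapsedRead(id=base, sequence=seq, count=int(suffix)))
    return out


# ---------------------------------------------------------------------------
# BED6


def write_bed(alignments: Iterable, path: str | Path) -> None:
    """Write alignments as BED6: chrom, start, end, name=read id, score=count, strand."""
    with xopen(path, "wt") as out:
        for a in alignments:
            out.write(
                f"{a.reference_id}\t{a.start}\t{a.end}\t{a.read_id}\t{a.count}\t{a.strand}\n"
            )


def read_bed(path: str | Path) -> list:
    """Read BED6 lines back into Alignment records (mismatches unknown → 0)."""
    from .alignment import Alignment

    out = []
    with xopen(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"malformed BED line {lineno}: expected 6 fields")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i, score_i = int(start), int(end), int(score)
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from exc
            if strand not in "+-":
                raise ValueError(f"malformed BED line {lineno}: bad strand {strand!r}")
            out.append(
                Alignment(
                    read_id=name,
                    reference_id=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    mismatches=0,
                    count=score_i,
                )
            )
    return out
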