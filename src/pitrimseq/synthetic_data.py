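"""Synthetic piRNA sequencing libraries with known trimming state.

Emulates the structure of matched wild-type / trimming-mutant MILI-IP small
RNA libraries: piRNA cluster references carrying planted loci with a strong
5'-U bias and Zipf-distributed abundance; mature (24-31 nt) reads in WT mode
versus genome-templated 3'-extended intermediates in mutant mode sharing the
mature 5' ends; 21-23 nt miRNA spike-ins; per-category decoy references and
reads; and 3' sequencing-adapter read-through on every read.  Every emitted
read has exactly one row in the truth table, which downstream tests use as
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (
    CATEGORIES,
    ReferenceSet,
    revcomp,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: NEBNext small-RNA 3' adapter prefix.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

TRUTH_COLUMNS = ["read_id", "locus_id", "cluster_id", "strand", "g5", "g3", "state", "category"]

# sub-stream keys appended to the user seed so no two stages share an RNG
_STREAM_REFERENCES = 11
_STREAM_WT = 13
_STREAM_MUTANT = 17
_STREAM_RANKS = 19


def truncated_geometric(p: float = 0.5, max_ext: int = 18) -> dict[int, float]:
    """Geometric(p) over extension lengths +1..+max_ext, renormalized.

    P(e) proportional to (1-p)^(e-1) * p.  This is the closed form the mutant
    3'-3' distance profile is checked against.
    """
    probs = {e: (1 - p) ** (e - 1) * p for e in range(1, max_ext + 1)}
    total = sum(probs.values())
    return {e: q / total for e, q in probs.items()}


def _default_mature_dist() -> dict[int, float]:
    # Mature MILI-bound piRNAs peak near 29-30 nt.
    return {26: 0.05, 27: 0.10, 28: 0.15, 29: 0.25, 30: 0.30, 31: 0.15}


def _default_decoy_sets() -> dict[str, tuple[int, int]]:
    # category -> (n_records, record_length)
    return {
        "coding_RNA": (15, 1500),
        "noncoding_RNA": (15, 500),
        "repeats": (15, 800),
        "intron": (15, 2000),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Distributions are dicts mapping value -> probability and must sum to 1.
    Mature lengths are confined to 24-31 nt and mature + max extension stays
    <= 49 so intermediates remain inside the 24-48 nt analysis window.

    ``min_locus_spacing`` is the minimum gap (nt) between planted locus
    intervals.  piRNA species are modeled as discrete, well-separated loci:
    a gap wider than the end-distance analysis half-window (30 nt) ensures
    each reference anchor is unambiguous, mirroring the single sharp
    position-0 peak that wild-type libraries show.
    """

    seed: int = 0
    n_clusters: int = 5
    cluster_length: int = 20_000
    n_loci_per_cluster: int = 60
    min_locus_spacing: int = 40
    mature_length_dist: dict[int, float] = field(default_factory=_default_mature_dist)
    extension_dist: dict[int, float] = field(default_factory=truncated_geometric)
    u_bias: float = 0.8
    abundance_exponent: float = 1.0
    n_reads: int = 50_000
    mirna_fraction: float = 0.05
    decoy_read_fraction: float = 0.08
    other_read_fraction: float = 0.02
    adapter: str = DEFAULT_ADAPTER
    decoy_sets: dict[str, tuple[int, int]] = field(default_factory=_default_decoy_sets)
    gc_content: float = 0.40
    untrimmed_mode: bool = False

    def __post_init__(self) -> None:
        for name, dist in (("mature_length_dist", self.mature_length_dist),
                           ("extension_dist", self.extension_dist)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        if min(self.mature_length_dist) < 24 or max(self.mature_length_dist) > 31:
            raise ValueError("mature lengths must lie in 24..31 nt")
        if min(self.extension_dist) < 1:
            raise ValueError("extensions must be >= +1 nt")
        if max(self.mature_length_dist) + max(self.extension_dist) > 49:
            raise ValueError("mature length + max extension must be <= 49 nt")
        if not 0.0 <= self.u_bias <= 1.0:
            raise ValueError("u_bias must be a probability")
        fracs = self.mirna_fraction + self.decoy_read_fraction + self.other_read_fraction
        if fracs >= 1.0:
            raise ValueError("spike-in fractions must leave room for piRNA reads")


@dataclass(frozen=True)
class Locus:
    """A planted piRNA-producing position inside a cluster reference."""

    locus_id: str
    cluster_id: str
    cluster_index: int
    strand: str
    start: int  # genomic interval [start, end), 0-based half-open
    end: int
    sequence: str  # mature sequence in locus orientation (5'->3')

    @property
    def g5(self) -> int:
        """5'-side interval bound: start on plus, end on minus."""
        return self.start if self.strand == "+" else self.end

    @property
    def g3(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class SimulatedReferences:
    """Reference sets plus the planted-locus ground truth."""

    sets: dict[str, ReferenceSet]
    loci: list[Locus]
    cluster_seqs: dict[str, str]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _sample_dist(rng: np.random.Generator, dist: dict[int, float], size: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in sorted(dist)])
    return keys[rng.choice(len(keys), size=size, p=probs / probs.sum())]


def build_references(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedReferences:
    """Generate cluster references with planted loci plus category decoys.

    Decoy sequences are rejection-sampled so that they share no 24-mer with
    any cluster sequence (either strand); reads drawn from them therefore
    annotate to their own category.  With ``out_dir`` set, one FASTA per
    category is written.
    """
    # distinct non-zero stream key: default_rng(s) and default_rng([s, 0])
    # collide, so every consumer of the seed gets its own key
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCES])
    max_ext = max(config.extension_dist)
    gap = config.min_locus_spacing

    cluster_seqs: dict[str, list[str]] = {}
    loci: list[Locus] = []
    for ci in range(config.n_clusters):
        cid = f"cluster{ci + 1}"
        seq = list(_random_seq(rng, config.cluster_length, config.gc_content))
        lengths = _sample_dist(rng, config.mature_length_dist, config.n_loci_per_cluster)
        occupied: list[tuple[int, int]] = []
        for li, mlen in enumerate(lengths):
            mlen = int(mlen)
            placed = False
            for _attempt in range(1000):
                strand = "+" if rng.random() < 0.5 else "-"
                # keep room for genome-templated downstream extension
                if strand == "+":
                    start = int(rng.integers(0, config.cluster_length - mlen - max_ext))
                else:
                    start = int(rng.integers(max_ext, config.cluster_length - mlen))
                end = start + mlen
                if all(end + gap <= s or start >= e + gap for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place locus {li} in {cid}: cluster too crowded"
                )
            occupied.append((start, end))
            # plant the 5'-U bias: the genomic base under the 5' end is T
            # with probability exactly u_bias, a uniform non-T base otherwise
            if rng.random() < config.u_bias:
                first = "T"
            else:
                first = "ACG"[int(rng.integers(3))]
            if strand == "+":
                seq[start] = first
            else:
                seq[end - 1] = revcomp(first)
            loci.append(
                Locus(
                    locus_id=f"{cid}_locus{li + 1}",
                    cluster_id=cid,
                    cluster_index=ci,
                    strand=strand,
                    start=start,
                    end=end,
                    sequence="",  # filled below, after all edits
                )
            )
        cluster_seqs[cid] = seq

    finalized: dict[str, str] = {cid: "".join(s) for cid, s in cluster_seqs.items()}
    loci = [
        Locus(
            locus_id=l.locus_id,
            cluster_id=l.cluster_id,
            cluster_index=l.cluster_index,
            strand=l.strand,
            start=l.start,
            end=l.end,
            sequence=(
                finalized[l.cluster_id][l.start : l.end]
                if l.strand == "+"
                else revcomp(finalized[l.cluster_id][l.start : l.end])
            ),
        )
        for l in loci
    ]

    cluster_kmers: set[str] = set()
    for seq in finalized.values():
        cluster_kmers |= _kmer_set(seq, 24)
        cluster_kmers |= _kmer_set(revcomp(seq), 24)

    sets: dict[str, ReferenceSet] = {
        "piRNA_cluster": ReferenceSet(
            category="piRNA_cluster",
            records=[(cid, finalized[cid]) for cid in sorted(finalized)],
            priority=1,
        )
    }
    for priority, category in enumerate(CATEGORIES[1:], start=2):
        n_records, length = config.decoy_sets.get(category, (0, 0))
        records = []
        for ri in range(n_records):
            for _attempt in range(50):
                seq = _random_seq(rng, length, config.gc_content)
                if not (_kmer_set(seq, 24) & cluster_kmers):
                    break
            else:
                raise RuntimeError(
                    f"rejection sampling failed for decoy category {category!r}: "
                    "decoys keep colliding with cluster 24-mers"
                )
            records.append((f"{category}_{ri + 1}", seq))
        sets[category] = ReferenceSet(category=category, records=records, priority=priority)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for category, refset in sets.items():
            write_fasta(refset.records, out_dir / f"{category}.fasta")

    return SimulatedReferences(sets=sets, loci=loci, cluster_seqs=finalized)


def simulate_library(
    config: SimulationConfig,
    references: SimulatedReferences,
    mode: str,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit one sequencing library (reads with 3'-adapter read-through) + truth.

    WT mode emits each locus's mature sequence; mutant mode emits the mature
    sequence plus downstream genomic bases, the extension length drawn from
    ``extension_dist`` (the untrimmed-intermediate model).  Read counts per
    locus follow a Zipf law over a single global rank list.  Spike-ins:
    21-23 nt miRNA decoys, per-category decoy-reference fragments, and
    unmappable random reads ("other").  The RNG stream is derived from
    ``config.seed`` and the mode, so WT and mutant libraries from one config
    are reproducible and distinct.

    Truth table columns: read_id, locus_id, cluster_id, strand, g5, g3,
    state, category.  g5/g3 are half-open interval bounds oriented by strand
    (plus: g5=start, g3=end; minus: g5=end, g3=start), so extended reads
    share g5 with their mature locus on either strand.
    """
    if mode not in ("WT", "mutant"):
        raise ValueError(f"mode must be 'WT' or 'mutant', got {mode!r}")
    rng = np.random.default_rng(
        [config.seed, _STREAM_MUTANT if mode == "mutant" else _STREAM_WT]
    )

    loci = references.loci
    clusters = references.cluster_seqs
    decoy_categories = [c for c in CATEGORIES[1:] if len(references.sets[c]) > 0]

    p_mirna = config.mirna_fraction
    p_decoy = config.decoy_read_fraction
    p_other = config.other_read_fraction
    p_pirna = 1.0 - p_mirna - p_decoy - p_other
    n_pirna, n_mirna, n_decoy, n_other = rng.multinomial(
        config.n_reads, [p_pirna, p_mirna, p_decoy, p_other]
    )

    # Zipf abundance over a single global rank permutation of loci; the
    # permutation is keyed on the seed alone: expression rank is a property
    # of the locus, shared by the WT and mutant libraries
    rank_of = np.random.default_rng([config.seed, _STREAM_RANKS]).permutation(len(loci))
    weights = (rank_of + 1.0) ** (-config.abundance_exponent)
    locus_counts = rng.multinomial(n_pirna, weights / weights.sum())

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    idx = 0

    def emit(insert: str, locus_id, cluster_id, strand, g5, g3, state, category) -> None:
        nonlocal idx
        idx += 1
        rid = f"r{idx:07d}"
        reads.append((rid, insert + config.adapter))
        truth_rows.append((rid, locus_id, cluster_id, strand, g5, g3, state, category))

    for locus, n in zip(loci, locus_counts):
        if n == 0:
            continue
        if mode == "WT":
            for _ in range(int(n)):
                emit(locus.sequence, locus.locus_id, locus.cluster_id, locus.strand,
                     locus.g5, locus.g3, "mature", "piRNA_cluster")
        else:
            exts = _sample_dist(rng, config.extension_dist, int(n))
            cseq = clusters[locus.cluster_id]
            for e in exts:
                e = int(e)
                if locus.strand == "+":
                    seq = cseq[locus.start : locus.end + e]
                    g3 = locus.end + e
                else:
                    seq = revcomp(cseq[locus.start - e : locus.end])
                    g3 = locus.start - e
                emit(seq, locus.locus_id, locus.cluster_id, locus.strand,
                     locus.g5, g3, "extended", "piRNA_cluster")

    # miRNA spike-ins: a small pool of distinct 21-23 nt species, Zipf counts
    n_species = 30
    mirna_pool = []
    for mi in range(n_species):
        length = int(rng.integers(21, 24))
        mirna_pool.append((f"mirna{mi + 1}", _random_seq(rng, length, config.gc_content)))
    w = (np.arange(n_species) + 1.0) ** (-1.0)
    for si, n in enumerate(rng.multinomial(int(n_mirna), w / w.sum())):
        mid, mseq = mirna_pool[si]
        for _ in range(int(n)):
            emit(mseq, mid, ".", ".", -1, -1, "spike_in", "miRNA_decoy")

    # decoy-category reads: plus-strand fragments of decoy references
    for _ in range(int(n_decoy)):
        category = decoy_categories[int(rng.integers(len(decoy_categories)))]
        refset = references.sets[category]
        rid_ref, rseq = refset.records[int(rng.integers(len(refset)))]
        length = int(rng.integers(24, 36))
        start = int(rng.integers(0, len(rseq) - length))
        emit(rseq[start : start + length], rid_ref, ".", "+",
             start, start + length, "decoy", category)

    # unmappable reads
    for _ in range(int(n_other)):
        length = int(rng.integers(24, 49))
        emit(_random_seq(rng, length, config.gc_content), ".", ".", ".",
             -1, -1, "decoy", "other")

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    logger.info("simulated %s library: %d reads (%d piRNA, %d miRNA, %d decoy, %d other)",
                mode, len(reads), n_pirna, n_mirna, n_decoy, n_other)
    return reads, truth


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of a SimulationConfig (dict keys stringified)."""
    d = asdict(config)
    d["mature_length_dist"] = {str(k): v for k, v in d["mature_length_dist"].items()}
    d["extension_dist"] = {str(k): v for k, v in d["extension_dist"].items()}
    return d
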