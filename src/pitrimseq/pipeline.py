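"""End-to-end orchestration: simulate -> preprocess -> annotate -> profile -> distance.

A run processes a matched pair of libraries (wild-type and trimming-mutant)
against one shared reference build, writes every stage output as TSV/BED
under the output directory, and records a ``manifest.json`` (config,
version, per-stage read ledgers) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .alignment import AlignConfig, Alignment, ReferenceIndex, align
from .annotation import AnnotationResult, annotate_hierarchical
from .distance_analysis import (
    ClusterPileup,
    DistanceProfile,
    ReferencePiRNA,
    cluster_pileup,
    distance_profile,
    select_reference_pirnas,
)
from .preprocess import ClipConfig, clip_reads, filter_by_length
from .profiles import (
    LengthDistribution,
    NucleotideComposition,
    first_nt_composition,
    length_distribution,
)
from .sequence_io import (
    CATEGORIES,
    CollapsedRead,
    collapse_reads,
    write_bed,
)
from .synthetic_data import (
    SimulatedReferences,
    SimulationConfig,
    build_references,
    config_to_dict,
    simulate_library,
)


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the analysis's stated settings:
    24-48 nt length window, one mismatch for annotation, perfect match for
    distance analysis, top 10000 anchors, a -30..+30 window, and a 21-23 nt
    miRNA-proxy for normalization."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_len: int = 24
    max_len: int = 48
    min_overlap: int = 6
    annotation_order: tuple[str, ...] = CATEGORIES
    annotation_max_mismatch: int = 1
    distance_max_mismatch: int = 0
    top_n: int = 10_000
    half_window: int = 30
    mirna_bounds: tuple[int, int] = (21, 23)
    multimap_weight: str = "full"
    flag_3p_positive_threshold: float = 0.5
    flag_5p_zero_threshold: float = 0.5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.distance_max_mismatch != 0:
            raise ValueError("distance analysis is defined for perfect matches only")


@dataclass
class LibraryBundle:
    """One library's processed state plus its count-weighted read ledger."""

    name: str
    collapsed: list[CollapsedRead]  # after clipping, before length filter
    filtered: list[CollapsedRead]  # 24-48 nt
    length_dist: LengthDistribution
    length_report: pd.DataFrame
    composition: NucleotideComposition
    annotation: AnnotationResult
    ledger: dict[str, int]
    reference_fingerprint: str
    truth: pd.DataFrame | None = None


@dataclass
class ComparisonReport:
    profile_5p: DistanceProfile
    profile_3p: DistanceProfile
    references: list[ReferencePiRNA]
    length_side_by_side: pd.DataFrame
    composition_side_by_side: pd.DataFrame
    trimming_defect: bool
    p5_mass_at_zero: float
    p3_positive_mass: float


@dataclass
class PipelineResult:
    config: RunConfig
    references: SimulatedReferences
    wt: LibraryBundle
    mutant: LibraryBundle
    comparison: ComparisonReport
    pileup: ClusterPileup
    manifest: dict


def _fingerprint(references: SimulatedReferences) -> str:
    h = hashlib.sha256()
    for cid in sorted(references.cluster_seqs):
        h.update(cid.encode())
        h.update(references.cluster_seqs[cid].encode())
    return h.hexdigest()[:16]


def process_library(
    name: str,
    raw_reads: Sequence[tuple[str, str]],
    references: SimulatedReferences,
    config: RunConfig,
    truth: pd.DataFrame | None = None,
) -> LibraryBundle:
    """Clip, collapse, profile, length-filter and annotate one library."""
    clip_cfg = ClipConfig(
        adapter=config.simulation.adapter,
        min_overlap=config.min_overlap,
        min_len=config.min_len,
        max_len=config.max_len,
    )
    clipped, tally = clip_reads(raw_reads, clip_cfg)
    collapsed = collapse_reads(clipped)
    ldist = length_distribution(collapsed, normalize=True, mirna_bounds=config.mirna_bounds)
    filtered, length_report = filter_by_length(collapsed, config.min_len, config.max_len)
    composition = first_nt_composition(filtered)
    ordered_sets = [references.sets[c] for c in config.annotation_order]
    annotation = annotate_hierarchical(
        filtered,
        ordered_sets,
        AlignConfig(max_mismatch=config.annotation_max_mismatch, strands="both", report="any"),
    )
    ledger = {
        "raw_reads": len(raw_reads),
        "clipped": tally["clipped"],
        "no_adapter_kept": tally["no_adapter"],
        "empty_after_clip_dropped": tally["empty_after_clip"],
        "clipped_kept": tally["clipped"] + tally["no_adapter"],
        "distinct_sequences": len(collapsed),
        "filtered_24_48": sum(r.count for r in filtered),
    }
    assert ledger["raw_reads"] == ledger["clipped_kept"] + ledger["empty_after_clip_dropped"]
    return LibraryBundle(
        name=name,
        collapsed=collapsed,
        filtered=filtered,
        length_dist=ldist,
        length_report=length_report,
        composition=composition,
        annotation=annotation,
        ledger=ledger,
        reference_fingerprint=_fingerprint(references),
        truth=truth,
    )


def compare_libraries(
    wt: LibraryBundle,
    query: LibraryBundle,
    references: SimulatedReferences,
    config: RunConfig | None = None,
) -> ComparisonReport:
    """WT-anchored comparison of a query library against a wild-type library.

    Selects the top-N uniquely mapped WT piRNAs as anchors and profiles the
    query's 5' and 3' ends around them.  The 3'-extension phenotype is
    flagged when the 3'-3' positive-offset mass and the 5'-5' mass at
    offset 0 both exceed their thresholds.
    """
    if config is None:
        config = RunConfig()
    if wt.reference_fingerprint != query.reference_fingerprint:
        raise ValueError("libraries were processed against different reference builds")
    index = ReferenceIndex(references.sets["piRNA_cluster"])
    refs = select_reference_pirnas(wt.filtered, index, n=config.top_n)
    kwargs = dict(
        cluster_references=index,
        half_window=config.half_window,
        multimap_weight=config.multimap_weight,
    )
    p5 = distance_profile(refs, query.filtered, end="5p", **kwargs)
    p3 = distance_profile(refs, query.filtered, end="3p", **kwargs)

    length = wt.length_dist.table.merge(
        query.length_dist.table, on="length", suffixes=(f"_{wt.name}", f"_{query.name}")
    )
    comp = pd.DataFrame(
        {
            "base": list(wt.composition.fractions),
            wt.name: list(wt.composition.fractions.values()),
            query.name: [query.composition.fractions[b] for b in wt.composition.fractions],
        }
    )
    p5_zero = p5.frequency_at(0)
    p3_pos = p3.mass(1, config.half_window)
    return ComparisonReport(
        profile_5p=p5,
        profile_3p=p3,
        references=refs,
        length_side_by_side=length,
        composition_side_by_side=comp,
        trimming_defect=(
            p3_pos > config.flag_3p_positive_threshold
            and p5_zero > config.flag_5p_zero_threshold
        ),
        p5_mass_at_zero=p5_zero,
        p3_positive_mass=p3_pos,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full matched WT/mutant analysis; write outputs if out_dir set."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    ref_dir = out_dir / "references" if out_dir else None
    references = build_references(config.simulation, ref_dir)

    bundles = {}
    for mode in ("WT", "mutant"):
        fastq = out_dir / f"{mode}.fastq" if out_dir else None
        truth_p = out_dir / f"{mode}.truth.tsv" if out_dir else None
        reads, truth = simulate_library(config.simulation, references, mode, fastq, truth_p)
        bundles[mode] = process_library(mode, reads, references, config, truth)

    comparison = compare_libraries(bundles["WT"], bundles["mutant"], references, config)

    # Fig-3D-style pileup: mutant long reads over WT short reads, first cluster
    index = ReferenceIndex(references.sets["piRNA_cluster"])
    perfect = AlignConfig(max_mismatch=0, strands="both", report="all")
    wt_alns = align(bundles["WT"].filtered, index, perfect)
    mut_alns = align(bundles["mutant"].filtered, index, perfect)
    first_cluster = references.sets["piRNA_cluster"].records[0][0]
    pileup = cluster_pileup(
        wt_alns,
        mut_alns,
        first_cluster,
        (0, config.simulation.cluster_length),
        known_clusters=set(references.cluster_seqs),
    )

    manifest = {
        "package": "pitrimseq",
        "version": __version__,
        "config": {
            "simulation": config_to_dict(config.simulation),
            "min_len": config.min_len,
            "max_len": config.max_len,
            "annotation_order": list(config.annotation_order),
            "annotation_max_mismatch": config.annotation_max_mismatch,
            "distance_max_mismatch": config.distance_max_mismatch,
            "top_n": config.top_n,
            "half_window": config.half_window,
            "mirna_bounds": list(config.mirna_bounds),
            "multimap_weight": config.multimap_weight,
        },
        "reference_fingerprint": _fingerprint(references),
        "ledgers": {name: b.ledger for name, b in bundles.items()},
        "n_reference_pirnas": len(comparison.references),
        "trimming_defect": comparison.trimming_defect,
    }

    result = PipelineResult(
        config=config,
        references=references,
        wt=bundles["WT"],
        mutant=bundles["mutant"],
        comparison=comparison,
        pileup=pileup,
        manifest=manifest,
    )
    if out_dir:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for bundle in (result.wt, result.mutant):
        bundle.length_dist.table.to_csv(
            out_dir / f"{bundle.name}.length_dist.tsv", sep="\t", index=False
        )
        bundle.length_report.to_csv(
            out_dir / f"{bundle.name}.length_report.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"base": list(bundle.composition.fractions),
             "fraction": list(bundle.composition.fractions.values())}
        ).to_csv(out_dir / f"{bundle.name}.first_nt.tsv", sep="\t", index=False)
        bundle.annotation.summary.to_csv(
            out_dir / f"{bundle.name}.annotation.tsv", sep="\t", index=False
        )
    cmp = result.comparison
    cmp.profile_5p.to_frame().to_csv(out_dir / "distance_5p.tsv", sep="\t", index=False)
    cmp.profile_3p.to_frame().to_csv(out_dir / "distance_3p.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (r.rank, r.sequence, r.cluster_id, r.strand, r.anchor5, r.anchor3, r.count)
            for r in cmp.references
        ],
        columns=["rank", "sequence", "cluster_id", "strand", "anchor5", "anchor3", "count"],
    ).to_csv(out_dir / "reference_pirnas.tsv", sep="\t", index=False)
    cmp.length_side_by_side.to_csv(out_dir / "length_comparison.tsv", sep="\t", index=False)
    cmp.composition_side_by_side.to_csv(
        out_dir / "first_nt_comparison.tsv", sep="\t", index=False
    )
    write_bed(result.pileup.track_a, out_dir / "pileup_wt_24_30.bed")
    write_bed(result.pileup.track_b, out_dir / "pileup_mutant_31_48.bed")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
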