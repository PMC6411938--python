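# Methods

## The problem

PIWI-interacting RNAs (piRNAs) are 24–32 nt germline small RNAs. Their 5′
ends are defined first; the 3′ ends of the PIWI-loaded precursors
(pre-piRNAs) are then shortened exonucleolytically to mature length. When
3′ trimming fails, immunoprecipitated PIWI-bound libraries contain
3′-extended intermediates that share the 5′ ends of mature piRNAs. This
package implements the sequencing-side diagnostics of that state: after
adapter clipping and a 24–48 nt length filter, reads are (i) annotated
hierarchically against ordered genomic reference sets, (ii) profiled by
miRNA-normalized length and first-nucleotide composition, and (iii)
subjected to 5′–5′ and 3′–3′ end-distance analysis against the most
abundant uniquely mapped wild-type piRNAs.

## Pipeline stages and parameters

**Adapter clipping** (`preprocess.clip_adapter`). The leftmost position at
which a prefix of the 3′ adapter (≥ `min_overlap` = 6 nt, 0 mismatches by
default) matches the read is found; everything 5′ of it is kept. Reads
with no adapter hit are retained: the 24–48 nt window includes
near-full-length inserts whose adapter may have fallen off the read end,
and discarding them would bias the 3′-extension signal. The retained
no-adapter count is reported so the effect is visible per run.

**Length filter**: 24–48 nt inclusive, applied count-weighted to collapsed
reads; the per-length retained/discarded report is an exact partition of
the input.

**Alignment** (`alignment.align`). Ungapped, substitution-only, both
strands by default. Two regimes: annotation allows one mismatch;
end-distance analysis requires perfect matches. The implementation is
seed-and-extend over an exact 12-mer index — for ≥ 24 nt reads and at most
one substitution, one of the two disjoint leading 12-mers must be exact
(pigeonhole), so no hit can be missed; shorter reads fall back to an
exhaustive scan. Correctness is defined by equivalence with
`brute_force_align`, a vectorized all-positions Hamming scan kept in the
production module but used as the oracle in tests.

**Hierarchical annotation** (`annotation.annotate_hierarchical`). Reads
are tested against the five reference sets in fixed priority order —
piRNA clusters, coding RNA, non-coding RNA, repeats, intron — and assigned
to the first set with ≥ 1 alignment; leftovers are "other". Assignment is
by alignment existence anywhere in the set (the sets are sequences, not
intervals, so no coverage threshold applies). Sequential filtering and
align-to-all-then-resolve give identical labels under this rule; the
sequential form is implemented. Percentages are count-weighted over all
filtered reads.

**Profiles** (`profiles`). The length histogram (18–48 nt) is scaled by
10⁶ / (total 21–23 nt reads): the miRNA proxy is purely length-defined,
and the reads-per-million scale is the field convention (the constant
cancels in any cross-library comparison; depth-duplication invariance is
exact). Normalizing a library with zero 21–23 nt reads is an error rather
than a silent zero. First-nucleotide composition is the count-weighted
base frequency at position 1 of the sequenced read over 24–48 nt reads,
with T reported as U; N-started reads are excluded from the denominator
and counted.

**End-distance analysis** (`distance_analysis`). Anchors are the top-N
(default 10 000) wild-type sequences with *exactly one* perfect-match
placement in the cluster set — "distinctively mapped" is read as uniquely
mapped, the only reading that yields unambiguous position-0 anchors; a
`unique_only=False` mode (any distinct mapped sequence) is also exposed.
Ties in abundance break by (count desc, sequence lexicographic). For each
perfect-match query placement on the same cluster and strand as an anchor,
the signed offset of the query's 5′ (or 3′) end from the anchor's matching
end is accumulated count-weighted for **every** anchor within the ±30 nt
window, then frequencies are normalized over in-window events. Offsets are
signed along the anchor's own 5′→3′ direction, so a 3′ extension is
positive on either genomic strand. Multi-mapping queries contribute all
placements at full count by default; a fractional 1/n-placements mode is
available. The pooled in-window denominator is a documented convention
chosen to make profiles comparable across library depths.

End coordinates are handled as strand-oriented half-open bounds (plus:
5′ = start, 3′ = end; minus: 5′ = end, 3′ = start); since query and anchor
use the same convention, offsets are exact base distances.

**Cluster pileup** (`distance_analysis.cluster_pileup`). Within a chosen
cluster region, 24–30 nt reads of one library and 31–48 nt reads of
another are emitted as ordered track pairs, and (5′ position, strand)
anchors occupied in both tracks are counted — the mature/intermediate
pairs the view exists to expose.

**Phenotype flag** (`pipeline.compare_libraries`). "3′-extension
phenotype" is reported when 3′–3′ positive-offset mass and 5′–5′ mass at
offset 0 both exceed their thresholds (default 0.5 each, configurable;
0 and 1 force the flag on/off for sanity checks).

## The synthetic-data generator

`synthetic_data` emulates matched wild-type / trimming-mutant
immunoprecipitated piRNA libraries and is the source of ground truth for
every test. What it models:

- **Clusters and loci.** Five 20 kb cluster sequences (40% GC), each with
  60 planted loci on random strands. Loci are non-overlapping with a
  minimum inter-locus gap of 40 nt — wider than the 30 nt analysis
  half-window — so every anchor is positionally unambiguous and the
  wild-type profile is a single position-0 peak up to sampling noise.
  Loci keep 18 nt of downstream genomic headroom so any drawn extension
  fits inside the cluster.
- **Mature lengths** from a categorical distribution peaked at 29–30 nt
  (range 24–31), matching MILI-bound piRNA sizing.
- **5′-U bias.** The genomic base under each locus 5′ end is set to T with
  probability `u_bias` (default 0.8) and to a uniform non-T base
  otherwise, so P(5′ = U) equals `u_bias` exactly, per locus. Because the
  indicator is drawn once per locus while abundance is Zipf-heavy, the
  read-weighted U fraction fluctuates far more than a read-count binomial
  would suggest; statistical checks of the bias are therefore made at the
  species level, where draws are i.i.d.
- **Abundance.** A Zipf law (exponent 1.0) over a single global rank
  permutation of loci. The permutation is keyed on the seed alone so
  wild-type and mutant libraries share locus ranks: expression is a
  property of the locus, not the genotype, and the mutant's intermediates
  accumulate on the same abundant loci that supply the wild-type anchors.
- **Trimming state.** WT mode emits each locus's mature sequence; mutant
  mode emits the mature sequence plus downstream *genome-templated* bases,
  the extension length drawn from a geometric(p = 0.5) distribution
  truncated to +1…+18 (the smeared, bounded 3′ extension of untrimmed
  intermediates; exposed as a free parameter since no quantitative law is
  established). Extended reads share the mature 5′ end by construction.
- **Spike-ins and decoys.** 5% of reads are 21–23 nt miRNA decoys (30
  species, Zipf counts) feeding the normalization; 8% are fragments of
  per-category decoy references (rejection-sampled to share no 24-mer
  with any cluster strand, so they annotate to their own category); 2% are
  random unmappable reads.
- **Read structure.** Every read carries the full 3′ adapter appended
  (NEBNext small-RNA adapter prefix by default); qualities are constant
  "I" since no stage uses them. Each emitted read has exactly one truth
  row (locus, cluster, strand, 5′/3′ bounds, mature/extended state,
  category).

What it does **not** model: sequencing errors, PCR duplicates, UMIs,
ping-pong biogenesis signatures, repeat-family structure, or the genomic
density of real piRNA clusters (real clusters produce overlapping,
heterogeneous 5′ ends; the generator's well-separated single-species loci
make anchor identity exact, which is the property the tests need). Passing
tests therefore demonstrate the correctness of the measurement machinery
on libraries with known structure, not the biology of any real dataset.

## Numerical and determinism choices

- All randomness flows from one integer seed through named, non-zero
  sub-stream keys (`[seed, k]`), one per stage; numpy collapses
  `SeedSequence(s)` and `SeedSequence([s, 0])` to the same state, so zero
  is never used as a key.
- Identical configuration ⇒ byte-identical FASTA/FASTQ/TSV outputs.
- Degenerate inputs fail loudly: empty reference list, zero in-window
  events (all-zero profile, flagged with a warning), zero miRNA-proxy
  reads, duplicate annotation priorities, unknown cluster ids, adapters
  shorter than the overlap minimum.
- Fewer qualifying anchors than requested returns all of them with a
  warning — at the default simulation scale there are a few hundred
  distinct species, so the top-10 000 request degrades gracefully.

## Problem sizes

The default simulated experiment is 50 000 reads per library over five
20 kb clusters, which the full pipeline processes in a few seconds; unit
tests use smaller scaled-down experiments (2 clusters × 6 kb, 4–5 k reads)
where only structure, not statistics, is under test. The aligner oracle
check runs 1000 random 24–48 nt reads against a 50 kb reference at both
mismatch settings.

## Known limitations

- The aligner is deliberately small-scale (reference sets of at most a few
  Mb); it is not a genome-scale indexer.
- The annotation stage has no repeat-family breakdown.
- "Distinctively mapped" anchors and the pooled in-window frequency
  denominator are documented interpretations (see above), each with an
  alternative mode exposed in configuration.
- Quality scores are parsed and validated but never used.
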