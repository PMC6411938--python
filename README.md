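# pitrimseq

Small-RNA-sequencing diagnostics for piRNA 3′-end trimming defects.

PIWI-interacting RNAs (piRNAs) mature in two steps: 5′-end formation, then
exonucleolytic 3′ trimming of the PIWI-bound pre-piRNA. When trimming
fails, immunoprecipitated PIWI libraries fill with 3′-extended
intermediates that still share the 5′ ends of mature piRNAs. `pitrimseq`
implements the sequencing analysis that detects this state, for people
analysing matched wild-type / mutant small-RNA libraries (or validating
such analyses against simulations with known truth):

- **Preprocessing** — 3′ sequencing-adapter clipping, read collapsing,
  24–48 nt length filtering.
- **Hierarchical annotation** — each read is assigned to the first of the
  ordered reference sets (piRNA clusters → coding RNA → non-coding RNA →
  repeats → intron, else "other") in which it aligns with ≤ 1 mismatch.
- **Profiles** — length histograms normalized to reads-per-million
  21–23 nt (miRNA) reads, and the first-nucleotide (1U) composition.
- **5′–5′ / 3′–3′ end-distance analysis** — the core statistic. The top-N
  uniquely mapped wild-type piRNAs define position 0; for a query library
  the frequency f(d) of read 5′ (or 3′) ends at signed offsets
  d ∈ [−30, +30] around those anchors is computed from perfect-match
  alignments, count-weighted, normalized over in-window events. A 5′
  profile with f(0) ≈ 1 and a 3′ profile with mass strictly at d > 0
  diagnoses shared 5′ ends with untrimmed 3′ ends.
- **Synthetic libraries** — a simulator that generates cluster references
  with planted piRNA loci (Zipf abundance, 5′-U bias), matched WT /
  untrimmed-mutant libraries with genome-templated 3′ extensions, miRNA
  spike-ins, decoy categories, and a per-read truth table.

## Worked example

```python
from pitrimseq import RunConfig, SimulationConfig, run_pipeline

result = run_pipeline(RunConfig(simulation=SimulationConfig(seed=1),
                                out_dir="demo"))
print(result.wt.annotation.summary.to_string(index=False))
cmp = result.comparison
print(f"5'-5' mass at 0:       {cmp.p5_mass_at_zero:.3f}")
print(f"3'-3' mass at d > 0:   {cmp.p3_positive_mass:.3f}")
print(f"3'-3' mass at d < 0:   {cmp.profile_3p.mass(-30, -1):.3f}")
print("trimming defect:", cmp.trimming_defect)
```

prints

```
     category  reads   percent
piRNA_cluster  42482 89.396267
   coding_RNA   1051  2.211654
noncoding_RNA   1036  2.180089
      repeats    957  2.013847
       intron   1006  2.116959
        other    989  2.081185
5'-5' mass at 0:       1.000
3'-3' mass at d > 0:   1.000
3'-3' mass at d < 0:   0.000
trimming defect: True
```

Read: ~89% of filtered wild-type reads map to piRNA clusters; the mutant
library's 5′ ends coincide exactly with the wild-type anchors (5′–5′ mass
1.0 at offset 0) while its 3′ ends lie strictly downstream (3′–3′ mass 1.0
at positive offsets, none negative) — the signature of a 3′-trimming
defect. `demo/` now holds per-stage TSVs (length distributions, first-nt
composition, annotation, distance profiles), BED tracks for the
mature-vs-extended cluster pileup, the simulated FASTQ/truth files, and a
`manifest.json` that reproduces the run byte-for-byte.

The same stages are available from the shell:

```
pitrimseq simulate --seed 1 --outdir sim
pitrimseq run --seed 1 --outdir out
pitrimseq distance --wt wt.fasta --query mut.fasta \
    --clusters sim/references/piRNA_cluster.fasta -o out/mut
```

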