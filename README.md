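# cnvseq

Copy-number analysis from shallow whole-genome sequencing of degraded
(FFPE) tumour DNA.

Archived formalin-fixed tumour material is usually the only biospecimen
available at population scale, but it yields fragmented, low-quantity DNA
on which allele-based copy-number methods struggle. `cnvseq` implements
the read-depth alternative end to end: aligned reads are binned into
fixed genomic windows, window counts are corrected for GC and mappability
bias, expressed as log2 ratios against a pooled "composite normal", and
segmented into copy-number events — with replicate-concordance and
germline-CNV genotyping utilities to quantify how trustworthy the
profiles are, and a seeded synthetic-data generator to validate every
stage against known truth.

## The method in brief

For sample *s* and window *w*, the read count `c_sw` is corrected per
chromosome by robust LOESS (local quadratic, Tukey biweight) on GC
content, then on mappability, giving adjusted counts `a_sw`. The
composite normal `N_w` is the sum of the pooled normal samples' counts,
corrected the same way. After scaling to equal totals the copy-number
signal is

    l_sw = log2( a_sw / N_w ),

missing on blacklisted windows (external problem regions; windows with
zero reads in >5% of samples; enclosed retained runs of <150 windows).
Circular binary segmentation finds, within each chromosome, the arc
maximising a two-sample t-like statistic against its complement, accepts
the split when its exact permutation p-value is below `alpha` (default
0.03, 10,000 permutations), recurses, and then removes change-points
whose adjacent means differ by less than `undo_sd` (default 3) times the
noise SD. A segment becomes a loss/gain call when its amplitude — the
segment mean minus the sample's chromosome median — clears 0.18 in
magnitude; per-region call patterns (single/double loss, loss plus extra,
focal gain, non-coding loss) follow a fixed taxonomy. See
`docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

Simulate a small cohort with one 400 kb deletion, run the pipeline, and
genotype nothing — just read off the call:

```python
from cnvseq import (SimConfig, GenomeSpec, CohortSpec, CNEvent,
                    simulate_counts, run_pipeline, PipelineConfig, GeneRegion)

cfg = SimConfig(
    genome=GenomeSpec(chromosomes=[("chr1", 3_000_000), ("chr2", 2_000_000)]),
    cohort=CohortSpec(n_tumours=2, n_normals=7, depth_per_window=100.0),
    window_size=10_000,
    events={"tumour01": [CNEvent("chr1", 1_000_000, 1_400_000, 0.25)],
            "tumour02": []},
    seed=314)
cm, truth = simulate_counts(cfg)

res = run_pipeline(cm, truth["normal_ids"],
                   PipelineConfig(n_permutations=2000, seed=1),
                   genes=[GeneRegion("TARGET", "chr1", 1_100_001, 1_200_000)])
for c in res.calls["tumour01"]:
    if c.direction != "none":
        print(c.chrom, c.start, c.end, c.direction,
              f"size={c.size_bp} amp={c.amplitude:.2f} genes={c.overlapped_genes}")
```

prints

```
chr1 1000000 1400000 loss size=400000 amp=-1.95 genes=('TARGET',)
```

— the deletion simulated at copy ratio 0.25 (log2 = −2) is recovered with
its exact 400 kb extent, chromosome-relative amplitude −1.95, and the
overlapped gene flagged. The event-free replicate `tumour02` yields only
`direction == "none"` segments.

The same stages are available as a CLI for file-based use:

```sh
cnvseq count --bam sample.bam --fai ref.fai --window-size 10000 --out counts.tsv
cnvseq annotate --fasta ref.fa --counts counts.tsv --out annotated.tsv
cnvseq blacklist --counts annotated.tsv --regions excl.bed --out mask.bed \
    --out-counts masked.tsv
cnvseq normalize --counts masked.tsv --normals n1,n2,n3,n4,n5,n6,n7 --out profiles.tsv
cnvseq segment --profiles profiles.tsv --alpha 0.03 --undo-sd 3 --out segments.seg
cnvseq call --segments segments.seg --profiles profiles.tsv --genes genes.bed \
    --out calls.tsv
```

plus `simulate`, `replicate`, `genotype-locus` and `sweep`.

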