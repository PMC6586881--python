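# Methods

`cnvseq` estimates DNA copy number from the density of aligned sequencing
reads in fixed genomic windows — the read-depth approach suited to
shallow whole-genome sequencing of degraded (FFPE) tumour DNA, where
allele-resolved methods are not an option. This note records the model,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Model and procedure

**Windowed counts.** The genome is tiled with non-overlapping windows of
fixed size (default 10 kb), anchored at coordinate 0 of each chromosome,
the terminal window truncated. Alignments that are unmapped, secondary,
supplementary, duplicate, QC-fail, or below mapping quality 20 are
discarded; each surviving read increments the single window containing
the midpoint of its aligned (clip-excluded) span, `floor((start + end − 1)/2)`,
the left-of-centre base for even spans. Counts are therefore conserved:
window sums equal retained reads, and counts at 1 kb windows aggregate
exactly to 10 kb counts.

**Bias correction.** Read depth varies smoothly with window GC content
(library-preparation bias) and mappability (uniqueness of k-mer
placement; gem-style reciprocal occurrence count at k = 35 with 1
mismatch, summarised as the per-window median). Each chromosome is
corrected independently by robust LOESS — local quadratic regression,
tricube distance weights over a span of 0.3, four Tukey-biweight
reweighting passes (tuning on 6×MAD-scaled residuals) — first on GC,
then on mappability. Correction is multiplicative
(`adjusted = count × reference / fitted`), keeping counts non-negative, with
the reference level chosen to preserve the per-chromosome median count.
Chromosomes with fewer than 30 informative windows pass through
unadjusted with a warning; non-positive fitted values flag windows
missing. The fit is evaluated on a ≤100-point covariate quantile grid and
interpolated; bias curves here are smooth, so the approximation error is
negligible against counting noise.

**Composite normal and log2 ratio.** The denominator of the copy-number
ratio is a composite normal: the element-wise sum of the pooled normal
samples' raw counts (seven in the intended design), corrected exactly
like a sample. Sample and composite are scaled to equal totals over
retained windows — so a predominantly diploid genome sits at log2 ≈ 0 —
and the per-window log2 ratio taken. Windows that are blacklisted, have
zero composite, or zero sample count are missing by default; a
configurable pseudocount (added to both scaled vectors) keeps
homozygous-deletion windows defined, and is what the validation
experiments use when simulating copy ratios near zero, where otherwise
the deleted windows themselves drop out of the profile.

**Blacklist.** Three monotone rules: (i) windows overlapping externally
supplied problem regions (≥1 bp, half-open); (ii) windows with zero reads
in strictly more than 5% of cohort samples; (iii) runs of retained
windows strictly shorter than 150 that are flanked on both sides by
blacklisted windows within a chromosome, applied to fixpoint. Runs
touching a chromosome end are not flanked and survive. The strict
inequalities and the both-sides reading of "flanked" are deliberate; the
fixpoint iteration is a design choice (a single pass can create new short
enclosed runs).

**Segmentation.** Circular binary segmentation per chromosome on the
finite log2 ratios. The maximal arc statistic
`U(i,j) = |T_j − T_i| / sqrt(L(1 − L/n))` (T the centred cumulative sum) is a
monotone transform of the pooled-variance two-sample t statistic between
arc and complement, because the total sum of squares is
permutation-invariant; maximising and permutation-testing U is therefore
exactly equivalent to doing so on t, and much cheaper. A split is
accepted when its exact permutation p-value (default 10,000 shuffles)
falls below alpha (default 0.03); the recursion continues on the
resulting pieces. Permutation seeds are keyed to the segment interval,
not to recursion order, so tightening alpha or the undo threshold can
only remove change-points — segment counts are monotone in both.

Two robustness devices frame the test. Before segmentation, isolated
outliers are clipped to within 4 noise SDs of a ±2-window running median;
at the low read depths this package targets, the log2 ratio has a heavy
left tail and lone extreme windows otherwise inflate the permutation null
(and with it the detection limit), while adjacent pairs of extreme
windows — real focal events — are measured against their normal
neighbourhood and survive the clip as a pair. After segmentation,
change-points whose adjacent segment means differ by less than
`undo_sd × noise SD` are removed greedily, weakest first, re-evaluating after
each merge. The noise SD is the normalised MAD (×1.4826) of lag-1
differences divided by √2 — insensitive to true copy-number steps.
Defaults alpha 0.03 and undo SD 3 follow the intended operating point; a
sweep harness scores any (alpha, SD) grid against reference calls
(sensitivity, specificity, call rate). Note the undo threshold is an
amplitude floor: with undo SD 3 and a typical noise SD of 0.2–0.35,
shallow broad losses (|Δ| ≲ 1 log2) are merged away — segmentation is
deliberately conservative, and sub-threshold subclonal losses are
expected misses.

**Calls and patterns.** A segment's amplitude is its mean log2 minus the
sample's chromosome median (whole-chromosome segments are 0 by
construction — chromosome-level aneuploidy is not called). Direction is
the amplitude's sign when |amplitude| ≥ 0.18, else none; the floor guards
against hairline segments and matches the smallest loss amplitude treated
as real in practice. Size is the genomic span. Within a target region
(e.g. the 9p21 cluster of MTAP/CDKN2A/CDKN2B), each sample receives one
pattern class with this precedence: double_loss (≥2 disjoint losses
hitting the anchor gene's coding span) → loss_plus_extra (one anchor loss
plus another loss elsewhere in the region) → single_loss → focal_gain
(gain of ≤2 windows over the anchor) → non_coding_loss (losses in the
region sparing the coding span) → none. Printed browser-style gene
coordinates (1-based inclusive) are converted to 0-based half-open by
`start − 1`; the printed gene span stands in for coding exons unless an
exon list is supplied.

**Concordance and genotyping.** Replicate pairs are compared by Pearson
correlation of corrected counts over jointly retained windows.
Significance is empirical: the null is the correlation of every distinct
cross-person sample pair (C(300, 2) = 44,850 pairs for a 300-person
single-sample cohort), with the add-one estimator
`p = (1 + #null ≥ r)/(1 + #null)` so p is never zero. A biallelic germline
deletion provides an internal truth standard: the per-sample ratio of
mean corrected counts over the deleted span (2 × 10 kb windows) to 10
flanking windows each side — flanks absorb somatic changes, and the ratio
is invariant to sample depth — is trimodal at 1, 0.5, 0 for 0/1/2 deleted
alleles. A 3-component Gaussian mixture (5 seeded restarts, variance
floor 1e-4) assigns genotypes by descending component mean. The number of
detected peaks is the count of local maxima of the fitted mixture density
after dropping components with weight < 2/n: the weight rule removes
degenerate components, and the density criterion merges overlapping ones,
so a cohort without the polymorphism reports one mode rather than three.
Copy-number-vs-expression association uses the two-sided Mann-Whitney U
test with the fold-change of group medians.

## Synthetic data: what it emulates, and what it does not

The generator draws per-window counts from a negative binomial with
`var = μ + φμ²` (φ default 0.05, emulating the overdispersion of
degraded-DNA libraries; φ = 0 gives Poisson), with
`μ = depth × copy_ratio × gc_bias(gc) × mappability`. The GC landscape is
sinusoidal (mean 0.45, amplitude 0.10, wavelength 200 kb) and the depth
bias in GC is unimodal quadratic peaking at 0.45 — the canonical
library-prep shape. Mappability dips come from exact duplicated blocks in
the simulated reference. Cohorts carry configurable somatic events per
tumour, seven event-free normals, and an optional germline deletion drawn
under Hardy-Weinberg. Alignment fixtures are SAM records whose midpoints
round-trip exactly through the counting filters.

Defaults mirror the intended study conditions: 10 kb windows at ~100
reads/window, 1 kb windows at ~18, seven pooled normals, 300-sample
genotyping cohorts at deletion-allele frequency 0.4. What the simulation
does **not** model: fragment-length structure and paired-end correlation,
FFPE deamination artefacts, melanin-driven library failure, tumour purity
and subclonality, reference gaps and centromeric repeat structure, and
real blacklist geography. Passing tests therefore demonstrate the
*algorithmic* contract — bias removal, detection limits at given
depth/dispersion, genotyping separability — not performance on any
particular real cohort.

## Validation experiments and problem sizes

The bundled experiments (tests and `scripts/acceptance.py`) use
desk-scale problems chosen to exercise each guarantee: 5,000-window
chromosomes for bias removal (post-correction |Spearman| < 0.05);
100 seeded replicates of a −2 log2 two-window dip in 400 windows of
N(0, 0.15) noise for boundary recovery (±1 window in ≥95%); exhaustive
oracle comparison for every arc on arrays up to length 12; 20-seed
majority spans for the focal detection-limit runs (4,000 × 1 kb windows
at 18 reads, 400 × 10 kb at 100 reads); and a 300-sample Hardy-Weinberg
cohort for genotyping (3 modes, ≥95% accuracy). The CBS permutation test
is exact at 10,000 permutations throughout; the pruned scan makes this
affordable even on the 4,000-window runs.

## Known limitations

* The undo threshold couples to the noise SD, so the minimum callable
  amplitude varies with depth; there is no absolute copy-number or
  purity/ploidy model.
* Exhaustive mappability is O(L²) and intended for desk-scale references;
  genome-scale tracks must be precomputed and read from BED-graph.
* The LOESS grid evaluation assumes a smooth bias curve; pathological
  covariate distributions (large gaps) fall back on nearest-window fits.
* Segmentation treats windows as exchangeable under the null; long-range
  autocorrelation (e.g. residual replication-timing bias) would make the
  permutation test anti-conservative.
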