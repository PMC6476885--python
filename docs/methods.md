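# Methods

## Window counting

Chromosomes are tiled into contiguous, non-overlapping 100-bp windows
(0-based half-open); the trailing partial window is kept so every
mapped read is countable. A read is assigned to exactly one window by
its 5′ mapped start coordinate — deterministic and appropriate for
short (~50 bp) single-end reads; a midpoint rule is available behind
the `assign="midpoint"` flag. Strand is ignored. Reads on unknown
chromosomes are skipped with a warning and counted. Windows whose
total count across all samples falls below `min_total` (default 10,
i.e. about one read per sample in a 12-pool design) are removed before
testing; the kept-index map preserves genome coordinates, and removed
windows re-enter region calling as p = 1.

## Exact negative-binomial window test

Counts are modeled NB(μ, φ) with Var = μ + φμ² and one common
dispersion φ shared by all windows; φ = 0 recovers the Poisson. The
choice of a single common dispersion (no per-window shrinkage) keeps
the test's character while avoiding empirical-Bayes machinery; it is a
documented divergence surface against tag-wise-moderated reference
implementations.

*Normalization.* Effective library sizes are total counts (default) or
total counts scaled by a trimmed mean of per-window log2 count ratios
against a reference sample (30% trim on the log-ratios, 5% on
abundance), factors normalized to geometric mean 1.

*Equalization.* Exact conditioning needs integer counts at a common
depth, so counts are scaled to the geometric mean of the effective
library sizes and rounded half-even — deterministic, so reruns are
bit-identical.

*Dispersion.* Because the sum of n i.i.d. NB(μ, φ) variables is
NB(nμ, φ/n), the distribution of a group's counts conditioned on the
group sum is free of μ. The single φ maximizes this pooled conditional
log-likelihood over all windows and both groups, with a bounded search
on [0, 10] (tolerance 10⁻⁴) and an explicit Poisson-limit evaluation
at φ = 0. Parameter-recovery tests cover φ ∈ {0, 0.1, 0.3} at 20,000
windows.

*Test.* Conditioning on a window's grand total T of equalized counts,
S₁ ~ NB(n₁μ̂, φ/n₁) and T − S₁ ~ NB(n₂μ̂, φ/n₂) with μ̂ = T/(n₁+n₂).
All T+1 splits are enumerated; the two-sided p-value sums the
normalized probabilities of every split no more probable than the
observed one (minimum-likelihood convention, ties included, relative
tie tolerance 10⁻¹²). Split tables are cached per unique total, which
makes genome-wide testing linear in practice. At φ = 0 and equal
library sizes this reduces exactly (to 10⁻¹²) to the conditional
binomial test; with φ > 0 and equal sizes it matches the reference
Bioconductor exact NB test to ~10⁻⁹ relative (frozen-value parity
test). Fold change is log₂ of normalized group means with a 0.5
pseudo-count. FDR is Benjamini–Hochberg across all tested (post-
filter) windows.

## DMR calling

Seeds are windows with p below `p_seed` (default 10⁻⁶; grid
{10⁻⁵…10⁻⁸} for the threshold table). Each seed's region extends
while any window with p < `p_extend` (0.1) lies within `extend_dist`
(1000 bp) of the region boundary, measured edge-to-edge; absorbing a
window absorbs everything between it and the region, so DMRs are
single contiguous intervals (the gapped alternative is deliberately
not produced — reported DMRs are coordinate intervals). Extended
regions that touch or overlap are merged, pooling seed windows. Each
DMR reports its seed count (`n_significant_windows`; ≥ 2 defines a
"multiple-window" DMR), minimum p and q, and maximum |log₂FC| over its
windows. The fast implementation is tested for exact agreement with a
naive global fixpoint oracle on 1000 random p-vectors.

## Permutation null and PCA

For each relabeling of the samples that preserves group sizes, the
*identical* analysis entry point is rerun — dispersion re-estimated
(it is label-dependent), windows tested, DMRs called — and the DMR
count recorded. Enumeration is exhaustive when C(n, n₁) ≤ `max_perms`
(924 labelings for 6v6), else labelings are sampled uniformly without
replacement. The empirical p-value is (1 + #{null ≥ observed}) /
(1 + n_permutations); it can never be zero. Both orientations of the
observed partition (the identity labeling and its complement, which
yields the same two-sided statistic by symmetry) are excluded from the
null counts, so an observed count larger than every null count reaches
exactly 1/(n+1).

A note on diagnostics at reduced scale: on a null dataset the DMR
count at the 10⁻⁶ seed threshold is degenerately zero, so the
null-uniformity diagnostic of the empirical p is run at a laxer seed
threshold (0.05) with 2,000 windows and 64 sampled permutations, where
the per-permutation count is non-degenerate and nearly free of ties
(ties make the +1-corrected p conservative), and the empirical p is
approximately uniform over replicate datasets.

PCA is computed on log₂(CPM + 1) of DMR windows only (whole-genome PCA
is available by calling the same routine on all windows), windows
centered, samples as observations, full SVD with deterministic sign
convention.

## Annotation and overlap

CpG content is a forward scan for the CG dinucleotide; density is per
100 bp; regions under 10 CpG/100 bp are flagged "CpG desert" (a
reporting-only flag, threshold configurable — the term is qualitative).
Gene association measures the edge-to-edge gap between the DMR and the
gene body and associates at ≤ 10 kb (overlap → 0), which covers
promoters via the flank; whether to measure to the TSS instead was an
open choice, and gene-body was selected because it needs no strand
model. Clusters are maximal runs of ≥ 3 DMRs with consecutive
start-to-start gaps ≤ 2 Mb (both parameters are this package's
defaults, exposed in the API). Cross-generation overlap is counted at
the region level: DMRs of 2–3 named sets overlapping by ≥ 1 bp chain
into connected components, and each component counts once in the Venn
cell of its membership pattern.

## Pathology scoring

Per observer and tissue, the cutoff is control mean + 2 sample SD
(n − 1 denominator; the SD convention was unstated upstream and is
documented here); an observer flags an animal on a *strict* exceedance
(ties are healthy), and a tissue is diseased on a 2-of-3 consensus.
Thresholds are computed from each generation's (and sex's) own
controls. Missing observers are an error — no imputation. Obesity
votes each of BMI (weight g / length cm²), the pooled mean of the 20
largest adipocyte areas per image, and the abdominal adiposity score
against control mean ± 1.5 SD per sex; ≥ 2 "high" votes classify
obese, ≥ 2 "low" lean (the 2-of-3 combination rule is this package's
choice — the source design lists the three measures and one cutoff
without a combination rule; the quorum is configurable). Frequencies
use two-sided Fisher exact tests, continuous measures pooled-variance
two-sided t-tests (zero pooled variance with equal means → p = 1,
with different means → flagged degenerate). Fertility rate is
pregnancies/breedings per lineage. Disease burden counts animals with
≥ 1 and ≥ 2 distinct disease flags (tissues plus obesity), with Fisher
comparisons against control.

## Synthetic data

The generators emulate the study's data structure at desk scale.

*Genome.* A CG-free background sequence is drawn, then CG pairs are
planted at binomially sampled non-overlapping even slots, with the
per-block (5 kb) expected density drawn from configurable levels
(defaults 1, 4, 10 CpG/100 bp) — giving desert and dense stretches
with exactly known CpG positions.

*Counts.* 6 pools per lineage (configurable); per-pool library sizes
log-normal around `mean_library_size` (CV 0.2) to mimic pool-to-pool
depth variation. Enrichment is monotone in CpG content,
λ_w ∝ exp(slope · CpG_w) capped — the minimal faithful model of
methylation-enrichment chemistry. Spiked regions (default 50, spans
1–5 windows, fold change 4, direction random) sit on window
boundaries ≥ 2 kb apart so truth is unambiguous under edge extension.
Counts are gamma-Poisson (NB) draws; φ = 0 gives exact Poisson. Each
pool is one NB sample — within-pool composition variance of the
pooled individuals is not modeled.

*Reads.* Each window/pool cell emits exactly its count of ~50-bp reads
with 5′ starts uniform in the window, so re-binning reproduces the
count matrix bit-for-bit (round-trip identity test).

*Scale.* The default per-pool depth (2×10⁵ reads) stands in for the
study-scale ~2×10⁷. Whole-pipeline demonstrations and the acceptance
script use a 2 × 250 kb genome (5,000 windows), chosen once by pilot
so per-window coverage (~40 reads/pool) is comparable to enriched
CpG-dense regions at study scale; at much sparser coverage a
fold-change-4 single-window seed cannot reach p < 10⁻⁶ for any data,
which is a property of the statistic, not of the implementation.
Validity (type-I) checks run at 50,000 windows where depth does not
matter.

*Cohorts.* Abnormality counts are overdispersed Poisson: each
animal × tissue draws a gamma multiplier (mean 1, variance
`observer_noise` = 0.05) shared by its three observers; the control
rate λ = 3 abnormalities per section reflects that trained observers
count several mild lesions even in healthy tissue, and — calibrated
once by pilot — makes the count informative enough that the 2 SD /
2-of-3 rule detects nearly all affected animals (a baseline of ~1
abnormality per section leaves the consensus rule under-powered for
any classifier, a property of the counts, not the implementation).
Affected exposed animals (default fraction 0.3) have λ multiplied by
`disease_effect` = 5. Obese animals (default 40% of exposed,
reflecting the transgenerational obesity frequencies such designs
report) shift BMI, adipocyte scale and adiposity by 2.5 control SD.
Parturition abnormality probabilities default to 0.03 (control) and
0.35 (exposed). These are stylized: real cohorts have correlated
pathologies across tissues, observer-specific biases, and age/litter
structure that the generator does not model — passing tests show the
scoring and statistics are correct under the stated model, not that
the biological effect sizes are realistic beyond their headline
frequencies.

## Determinism and numerics

Every generator and the pipeline take explicit integer seeds; reruns
with the same config and seed produce byte-identical summary JSON.
Rounding is half-even everywhere; probability ties in exact tests use
a 10⁻¹² relative tolerance; p-values are clipped to (0, 1] and the
least extreme outcome gets p exactly 1.

## Known limitations

- Common dispersion only; no tag-wise moderation, GLM mode, or
  covariates.
- Enumeration cost is linear in a window's equalized total, so
  extremely deep single windows (≫10⁴ reads) are slow; the intended
  regime is tens-to-hundreds of reads per window.
- Gene association uses gene bodies, not TSS/strand.
- Venn overlap supports 2–3 sets.
- The obesity combination rule and cluster parameters are package
  choices, exposed as configuration.
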