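# Methods

This note documents the models implemented in `hapdmr`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## The biological setting

At a locus with haplotype-dependent allele-specific methylation
(hap-ASM), the DNA sequence of each haplotype influences whether the
surrounding CpGs become methylated. An individual therefore has one of
three *epigenotypes* — both alleles methylated, one, or neither — and a
bulk WGBS measurement of such a region reads out near 1.0, 0.5 or 0.0,
blurred by cell-to-cell heterogeneity (epigenetic mosaicism), finite
coverage and imprecise region borders. Across a small cohort, a region
where epigenotypes segregate like a Mendelian locus shows large
*inter-individual* differences even though every single methylome looks
internally consistent.

## DMR calling on extreme envelopes

With only a handful of samples and no group labels, a two-group test is
ill-posed. Instead two synthetic methylomes are formed per cohort — the
per-CpG maximum and minimum levels — and their difference
t(c) = max(c) − min(c) is the per-CpG signal. Regions are maximal runs
of consecutive aligned CpGs with t(c) > v; the run is broken when the
next CpG is more than `max_gap` away or on another chromosome.

Parameters (defaults):

| parameter | default | meaning / rationale |
|---|---|---|
| `v` | 0.5 | per-CpG envelope threshold; 0.5 separates "one vs both alleles methylated somewhere in the cohort" from noise |
| `min_cpgs` | 4 | minimum member CpGs; single-CpG differences are dominated by measurement noise |
| `min_core_diff` | 0.8 | envelope core-methylation difference; implies one homozygously methylated and one homozygously unmethylated individual |
| `max_gap` | 300 bp | within-region gap bound; the convention of smoothing-based WGBS callers, since the statistic itself does not bound gaps |
| `min_cov` | 3 | per-sample coverage floor at alignment; suppresses single-read noise while keeping desk-scale fixtures valid |

The *core methylation* of region d in sample i is the σ(c)-weighted
average of member-CpG levels, where σ(c) is the cross-sample standard
deviation. High-σ CpGs are the ones that actually discriminate
individuals, so the weighting makes μ robust to imprecise borders
(border CpGs have low σ and contribute little). We normalize by Σσ(c),
making μ a convex combination and hence μ ∈ [0, 1] — a property the
beta-mixture stage requires. A variant that divides by |C(d)| instead
(not scale-free, can leave [0, 1]) is available as
`core_normalization="printed"` for compatibility with descriptions that
write the prefactor 1/|C(d)|.

σ(c) is the *population* standard deviation (divide by n, not n − 1):
it stays defined for two samples and is bounded by 0.5 for levels in
[0, 1]. It is switchable (`sigma_ddof`). Sites not covered at
`min_cov` in every sample are dropped, not imputed, because max/min
require a defined level in all samples. Ties in max/min are irrelevant
(values, not sample identities, enter the statistic). An optional
coverage-weighted boxcar smoother is provided but off by default: the
envelope statistic and the binomial null operate on raw levels, and
smoothing before taking extremes changes the null distribution.

DMR coordinates are reported as the span of member CpGs (1-based first
to last member; BED output converts to 0-based half-open). Padding
borders outward would be arbitrary without a model of border shape.

## Empirical significance

The null hypothesis is "no inter-individual difference": every sample's
count at CpG c is binomial at the pooled rate p_c with the *observed*
coverage n_{s,c}. This preserves the coverage structure exactly, so the
only variation in a null replicate is finite-sampling noise. The caller
runs on R = 1000 replicate cohorts; k = number of replicates with at
least one qualifying call anywhere. Every observed DMR gets p = k/R,
reported as the bound 1/R when k = 0. This family-level definition
("any qualifying call anywhere") is deliberately conservative for the
individual region and reproduces the "p < 0.001 for each DMR" style of
reporting exactly when k = 0. Two variants are provided:
`counting="per_region"` counts only null calls overlapping the specific
observed DMR, and `conservative=True` uses (k+1)/(R+1), the standard
never-zero permutation estimator.

The replicate stream derives from one seeded generator, so a run is
reproducible end to end from its seed.

## Detection-rate model and extrapolation

Assume one causal biallelic SNP per DMR, epigenotypes in Hardy–Weinberg
proportions (p², 2pq, q²), and that the caller needs at least one
homozygously methylated and one homozygously unmethylated individual
among n. Inclusion–exclusion on the complementary event gives

P(p, q) = 1 − [(1 − p²)ⁿ + (1 − q²)ⁿ − (2pq)ⁿ].

P is symmetric in p ↔ q, zero at n = 1 and monotone non-decreasing in
n. Averaging P over an allele-frequency spectrum (supplied as a TSV;
e.g. common SNPs with MAF > 0.05) yields the detectable fraction of
DMRs, and observed/rate extrapolates the population total. The value is
clipped to [0, 1] against floating-point rounding; at n = 1 a residual
of order 1e−16 remains rather than an exact 0.

## Beta-mixture epigenotype scoring

Core methylations of all called DMRs across all samples are pooled and
fitted with a three-component beta mixture — fitting per DMR is
impossible with five values. The posterior L(g, μ) of class g given μ
then replaces any hard threshold for calling a sample's epigenotype,
and the SNP–DMR score is the product of per-sample posteriors. The
score is ≤ every factor, so a single discordant sample vetoes the pair
— appropriate when a perfect Mendelian relationship is the hypothesis.

Fitting is EM with an exact M-step: for each component the weighted
beta log-likelihood is concave in (α, β), and a damped Newton iteration
on the digamma stationarity conditions solves it to machine precision,
keeping the EM log-likelihood monotone (`ll_trace` records it).
Initialization is method-of-moments on the value blocks split at 1/3
and 2/3; 4 additional restarts jitter the split points (uniform ±0.08,
seeded), and the best log-likelihood wins. Values are clamped to
[1e−6, 1 − 1e−6]; convergence at Δloglik < 1e−8 or 500 iterations;
parameters clipped to [1e−3, 1e6]; a fit with non-increasing component
means (collapsed components) triggers a RuntimeWarning rather than a
silent NaN; identical inputs raise.

Scoring choices:

* **Orientation.** Which SNP allele carries methylation differs per
  locus, so by default both mappings g → class g and g → class 2 − g
  are evaluated and the larger product kept, with the orientation
  reported. A fixed orientation is available.
* **Missing genotypes** drop that sample's factor from the product
  (`n_samples_used` flags reduced support) instead of discarding the
  SNP — in a five-sample cohort a whole-SNP drop would be too costly.
  Scores with different missingness are not directly comparable.
* **Window.** SNPs within ±6 kb of the DMR center (midpoint of the
  member-CpG span), boundary inclusive. The threshold 0.9 is
  calibrated for n = 5 — the maximal product of five posteriors of a
  truly concordant SNP is slightly below 1, while one discordant
  sample pushes the product near 0; for other n the threshold is a
  parameter, since the product scales with n.

## Flank profiles and enrichment

Flank profiling skips the 3 aligned CpGs on each side of a DMR (border
blur) and averages the next 10; a side with fewer than 10 available
CpGs on its chromosome makes the profile `incomplete`. Comparisons are
strict: equality with a flank is `intermediate`, never
lower/higher-than-both. Flank means use the per-CpG cross-sample mean
(pooled); per-sample levels are available from the cohort matrix if
needed.

Enrichment uses matched random region sets: lengths resampled with
replacement from the observed DMR sizes, placed uniformly subject to
avoiding the repeat mask and covering ≥ 4 CpGs (the caller's own
constraints, so the null regions are "callable" regions). One region
set per null replicate, `regions_per_set` defaulting to the observed
DMR count. p_over / p_under are the fractions of null sets with
strictly higher / strictly lower overlap counts; ties count toward
neither, so p_over + p_under ≤ 1. Overlap is ≥ 1 bp intersection.
Placement uses vectorized batch rejection over precomputed sorted
interval arrays, which keeps even 10⁴–10⁶ sets tractable; the default
is 10,000 sets at desk scale with the count exposed as a flag.

Group comparisons (flank vs DMR methylation, state-concordant vs
state-discordant methylation differences) use the Wilcoxon rank-sum
test: exact null for combined sizes ≤ 20 without ties, tie-corrected
normal approximation otherwise. A DMR is state-"different" between two
donors iff its overlapping state-label sets are disjoint.

## The synthetic cohort generator

The generator emulates the study conditions the pipeline targets — a
five-sample, single-cell-type, single-sex WGBS cohort at ~30× coverage
— so every stage is testable without restricted human data.

| aspect | model | default |
|---|---|---|
| CpG spacing | exponential gaps | mean 100 bp |
| coverage | Poisson truncated ≥ 1 | λ = 30 |
| background methylation | per-CpG Beta(a, b) mean, shared by all samples | mean 0.72, concentration 10 |
| planted DMRs | 4–20 consecutive CpGs, internal gaps ≤ 280 bp | 10 per genome |
| causal SNP | uniform within ±2 kb of DMR center | — |
| genotypes | Hardy–Weinberg, Binomial(2, MAF) | MAF 0.5 |
| epialleles | per-read Bernoulli, m_hi / m_lo | 0.95 / 0.05 |
| mosaicism ε | per-read epiallele flip | 0.0 |

Choices worth noting:

* **Read-level model.** At a planted CpG each read picks one of the
  two alleles with probability 1/2 and is methylated with that
  epiallele's probability, so counts are *exactly* binomial given the
  genotype — the same family as the caller's null, which makes null
  calibration checks meaningful. `simulate_site_reads` exposes the
  per-read allele assignments so that sorting reads by allele
  reproduces the read-level allele-specific methylation split used to
  validate such regions experimentally.
* **Coherent planted blocks.** Planted members are chosen from CpG
  runs whose internal gaps stay below the caller's 300 bp `max_gap`
  (≤ 280 bp), emulating the CpG-coherent regulatory elements where
  hap-ASM occurs; without this a planted region could straddle a
  caller-level gap break by construction, which would test the gap
  parameter rather than recovery.
* **Hypermethylated background** (mean 0.72) matches the empirical
  flank level of such regions and gives the flank-profile analysis
  signal to detect. The background mean is drawn once per site and
  shared by all samples, so background sites carry *no*
  inter-individual signal: any call there is a false positive, and
  chromosomes without planted regions (all but the first) are exact
  negative controls.
* **Mosaicism defaults to 0** — no quantitative estimate is available
  to set it; the parameter is exposed, and raising it shrinks the
  effective m_hi − m_lo separation.
* One seeded generator drives the whole cohort; every stochastic
  operation accepts an explicit seed.

What the generator does **not** emulate: sequencing and
bisulfite-conversion errors, read-length/fragment structure, mappability
and repeat-driven coverage bias, correlated methylation beyond the
planted blocks (no COMET/block autocorrelation in the background),
cell-type mixtures, or linkage disequilibrium among SNPs (background
SNP genotypes are independent). Passing the recovery tests therefore
shows the pipeline's statistical machinery is correct under its own
model assumptions, not that real-data artifacts are handled.

## Problem sizes used in the validation suite

The test and acceptance runs use desk-scale versions of the analysis,
chosen once as sizes a laptop handles comfortably while keeping every
statistical check well-powered: a ~20,000-CpG five-sample cohort with
20 planted regions for the 1000-replicate null (where no replicate
yields any call, reproducing the p < 0.001 bound); 200 cohorts of 8
planted regions on 200 kb for region/SNP recovery; 500 random cohorts
of ≤ 200 sites for brute-force caller equivalence; 1000 repetitions ×
200 null sets for enrichment self-calibration (where the enrichment
p value must be uniform when the "observed" regions are themselves
random). The negative-control permutation in the SNP-scoring check
resamples a random permutation until the dosage vector actually
changes: with five samples dosage vectors have heavy ties, and a
shuffle that reproduces the identical vector has not broken the
genotype–methylation link, so it is uninformative as a negative
control. Orientation-flip coincidences remain and are counted against
the specificity bound.

## Known limitations

* The caller has no model of biological replicate variance — it is
  designed for exactly the no-labels, few-samples setting; with group
  structure a smoothed two-group statistic is more appropriate.
* The family-level empirical p is a bound, not a per-region tail
  probability; with k > 0 the per-region variant is the more
  interpretable choice.
* The detection model assumes a single causal SNP and perfect
  penetrance of epigenotypes; mosaicism or multi-SNP control deflates
  the detectable fraction below P(p, q).
* The product score is not comparable across SNPs with different
  numbers of non-missing samples, and with five samples coincidental
  genotype matches occur (a score > 0.9 is a hypothesis, not a proof —
  validation needs more individuals or read-level evidence).
* Beta-mixture fitting needs enough called DMRs (≥ 3 values per
  component; in practice ≥ 2 DMRs × 5 samples) and all three
  epigenotype classes represented in the pool; otherwise components
  collapse and the fit is flagged.
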