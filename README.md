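# hapdmr

Discovery of **regions of common inter-individual DNA methylation
differences** from small whole-genome bisulfite sequencing (WGBS)
cohorts, and attribution of those regions to genotype via a beta-mixture
epigenotype score.

The package is aimed at epigenomics groups who have a handful of deeply
sequenced methylomes (the motivating design is five male monocyte WGBS
datasets) rather than the hundreds of samples a classical mQTL study
needs, and who want to find loci where methylation differs *between
individuals* because of haplotype-dependent allele-specific methylation
(hap-ASM).

## Method

**Extreme-methylome DMR calling.** From per-CpG methylation levels
m_i(c) of samples i = 1..n, two synthetic methylomes are built: one with
the highest level of each CpG across samples, one with the lowest. The
per-CpG statistic is the difference of the envelopes,

    t(c) = max(c) − min(c),

and candidate regions are maximal runs of consecutive CpGs with
t(c) > v (default v = 0.5), broken at gaps > 300 bp. A region d with
CpG set C(d) is kept when |C(d)| ≥ 4 and the σ-weighted *core
methylation* difference between the two envelopes is ≥ 0.8, where

    μ_i(d) = Σ_{c∈C(d)} σ(c) m_i(c) / Σ_{c∈C(d)} σ(c)

and σ(c) is the cross-sample standard deviation of the level at c. A
0.8 envelope difference implies at least one individual is homozygously
methylated and another homozygously unmethylated across the region.

**Empirical null.** Under "no inter-individual difference", each
sample's count at CpG c is Binomial(n_{s,c}, p_c) at the pooled rate
p_c = Σ_s m_{s,c} / Σ_s n_{s,c}, with coverage matched site-by-site to
the observed data. The caller is run on R = 1000 such replicate
cohorts; each observed DMR receives empirical p = k/R where k is the
number of replicates with any qualifying call, reported as the bound
1/R when k = 0 (i.e. *p* < 0.001).

**Detection-rate model.** With one causal biallelic SNP per DMR and
Hardy–Weinberg epigenotypes, the design detects a DMR only when both
homozygote classes appear among n samples:

    P(p, q) = 1 − [(1 − p²)ⁿ + (1 − q²)ⁿ − (2pq)ⁿ],  q = 1 − p.

Averaged over an allele-frequency spectrum this gives the detectable
fraction, and observed count / rate extrapolates the total number of
such regions in the population.

**Epigenotype scoring.** Pooled core methylations of all called DMRs
are decomposed into a three-component beta mixture (unmethylated /
half- / full-methylated). For a SNP s with dosages g_i(s), the
co-variation score is the product of posteriors

    score(s, d) = Π_i L(g_i(s), μ_i(d)),

evaluated for every SNP within ±6 kb of the DMR center; score > 0.9
calls the SNP correlated. Both genotype→class orientations are tried,
since either allele may carry the methylation.

**Region statistics.** Flank profiling (skip 3 CpGs beyond each border,
average the next 10) classifies each DMR against its surroundings, and
annotation enrichment is assessed against random region sets matched to
the observed size distribution, placed outside the repeat mask on ≥4
CpGs, with empirical over/under-representation p values and Wilcoxon
rank-sum group comparisons.

**Synthetic cohorts.** Because real WGBS cohorts of this kind are
access-restricted, `hapdmr.simulate` generates fully specified
stand-ins: exponential inter-CpG spacing, hypermethylated Beta
background (mean 0.72), truncated-Poisson coverage (mean 30), and
planted DMRs whose per-read methylation follows Hardy–Weinberg
genotypes at a nearby causal SNP (epialleles 0.95/0.05). Ground truth
is emitted for recovery testing.

## Worked example

```python
from hapdmr.pipeline import RunConfig, run_pipeline
from hapdmr.simulate import SimulationParams

cfg = RunConfig(
    outdir="hapdmr_demo", seed=17,
    sim=SimulationParams(chrom_lengths={"chr1": 250_000}, n_planted_dmrs=8),
    null_replicates=1000, enrichment_sets=2000,
)
res = run_pipeline(cfg)
print(res.dmr_table[["dmr_id", "chrom", "start", "end", "n_cpgs",
                     "envelope_diff", "p_value", "p_is_bound"]])
```

```
dmr_id chrom  start    end  n_cpgs  envelope_diff  p_value  p_is_bound
  dmr1  chr1  27772  28795      10          0.909    0.001        True
  dmr2  chr1 115638 116572      11          0.955    0.001        True
  dmr3  chr1 236020 236174       4          0.877    0.001        True
```

Three of the eight planted regions are called — as expected: with five
samples at allele frequency 0.5 only ~56% of loci sample both
homozygote epigenotypes, the design's detection limit. None of the 1000
binomial null replicates produced a call (k = 0), so each DMR carries
the bound *p* < 0.001 (`p_is_bound`). The SNP scores recover each
region's causal SNP with its orientation:

```
      snp_id dmr_id    pos  distance  score    orientation
planted1_snp   dmr1  28822     538.5    1.0 alt_methylated
planted5_snp   dmr2 115345     760.0    1.0 ref_methylated
planted8_snp   dmr3 234375    1722.0    1.0 ref_methylated
        bg88   dmr3 237976    1879.0    1.0 alt_methylated
```

(`bg88` is a background SNP whose five dosages happen to match dmr3's
epigenotypes — with five samples such coincidental hits are expected
occasionally, which is why small-cohort correlations need validation.)
Flank profiles show the characteristic pattern of allele-specific
regions punched into a methylated background — a DMR mean near 0.5
flanked by ~0.7 methylation:

```
dmr_id  dmr_mean  upstream  downstream  classification
  dmr1     0.488     0.740       0.687  lower_than_both
  dmr2     0.493     0.689       0.707  lower_than_both
  dmr3     0.602     0.691       0.713  lower_than_both
```

The same stages are available as a CLI:
`hapdmr simulate | align | call | pvalue | detect-rate | score | flanks |
enrich | state-diff | run`.

## Layout

- `hapdmr.io` — Bismark-coverage/bedGraph methylomes, VCF/TSV genotypes,
  BED annotations, cohort alignment
- `hapdmr.simulate` — synthetic cohorts with planted hap-ASM
- `hapdmr.caller` — extreme-envelope DMR calling
- `hapdmr.significance` — binomial empirical null, detection-rate model
- `hapdmr.scoring` — beta-mixture fit, posterior SNP–DMR scores
- `hapdmr.regions` — flank profiles, matched-region enrichment,
  rank-sum comparisons
- `hapdmr.pipeline` / `hapdmr.cli` — orchestration and shell interface

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
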