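"""Empirical significance of called DMRs and the Hardy-Weinberg
detection-rate model.

Empirical null
--------------
Under the null hypothesis of no inter-individual difference, every
sample's methylation count at CpG c is a binomial draw at the pooled rate

    p_c = sum_s m_{s,c} / sum_s n_{s,c},

with the coverage of each null sample matched exactly to the observed
sample it mirrors. The DMR caller is applied to R such replicate cohorts
(default R = 1000); with k the number of replicates producing at least
one qualifying DMR anywhere, every observed DMR receives the empirical
p value k/R, reported as the bound 1/R when k = 0 (so k = 0, R = 1000
yields "p < 0.001" for each DMR).

Detection-rate model
--------------------
Assuming one causal biallelic SNP per DMR and Hardy-Weinberg genotype
frequencies (p^2, 2pq, q^2), the caller can only find a DMR when at
least one of n samples is homozygous for each epiallele. By
inclusion-exclusion on the complementary event,

    P(p, q) = 1 - [(1 - p^2)^n + (1 - q^2)^n - (2pq)^n].

Averaging P over an allele-frequency spectrum (e.g. dbSNP SNPs with
MAF > 0.05) gives the expected fraction of detectable DMRs, and the
observed DMR count divided by that rate extrapolates the total number of
such regions in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import DMR, CallerParams, _qualifying_runs
from .io import CohortMatrix

COUNTING_MODES = ("any_region", "per_region")


def pooled_rates(cohort: CohortMatrix) -> np.ndarray:
    """Per-site pooled methylation rate p_c = total meth / total coverage."""
    tot_cov = cohort.cov.sum(axis=0)
    assert (tot_cov > 0).all(), "aligned sites must have positive coverage"
    return cohort.meth.sum(axis=0) / tot_cov


def simulate_null_replicate(
    cohort: CohortMatrix, p_c: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One coverage-matched binomial null count matrix (shape of cohort.meth)."""
    return rng.binomial(cohort.cov, p_c[None, :])


@dataclass
class NullResult:
    """Summary of the empirical-null procedure."""

    R: int
    k: int  # replicates with >=1 qualifying DMR anywhere
    null_call_counts: np.ndarray = field(repr=False)  # (R,) DMRs per replicate
    p_values: np.ndarray = field(repr=False)  # per observed DMR
    p_is_bound: np.ndarray = field(repr=False)
    counting: str = "any_region"
    conservative: bool = False


def empirical_pvalues(
    cohort: CohortMatrix,
    params: CallerParams | None = None,
    R: int = 1000,
    seed: int = 0,
    dmrs: list[DMR] | None = None,
    counting: str = "any_region",
    conservative: bool = False,
) -> tuple[list[DMR], NullResult]:
    """Assign empirical p values to observed DMRs from R null replicates.

    ``counting="any_region"`` (default) counts replicates yielding a
    qualifying DMR anywhere in the genome; ``"per_region"`` counts, for
    each observed DMR separately, replicates yielding a null DMR that
    overlaps its span. ``conservative`` uses (k+1)/(R+1) instead of k/R.
    DMRs are annotated in place and returned.
    """
    from .caller import call_dmrs

    if R < 1:
        raise ValueError("R must be >= 1")
    if counting not in COUNTING_MODES:
        raise ValueError(f"counting must be one of {COUNTING_MODES}")
    params = params or CallerParams()
    if dmrs is None:
        dmrs = call_dmrs(cohort, params)
    p_c = pooled_rates(cohort)
    rng = np.random.default_rng(seed)
    n_dmrs = len(dmrs)
    null_counts = np.zeros(R, np.int64)
    per_region_k = np.zeros(n_dmrs, np.int64)
    spans = [(d.chrom, d.start, d.end) for d in dmrs]
    for r in range(R):
        meth = simulate_null_replicate(cohort, p_c, rng)
        level = meth / cohort.cov
        runs = _qualifying_runs(level, cohort.pos, cohort.chrom_id, params)
        null_counts[r] = len(runs)
        if counting == "per_region" and runs:
            for j, (chrom, start, end) in enumerate(spans):
                for a, b in runs:
                    if (
                        str(cohort.chrom[a]) == chrom
                        and cohort.pos[a] <= end
                        and cohort.pos[b - 1] >= start
                    ):
                        per_region_k[j] += 1
                        break
    k = int((null_counts > 0).sum())
    if counting == "any_region":
        ks = np.full(n_dmrs, k, np.int64)
    else:
        ks = per_region_k
    if conservative:
        p = (ks + 1) / (R + 1)
        bound = np.zeros(n_dmrs, bool)
    else:
        bound = ks == 0
        p = np.where(bound, 1.0 / R, ks / R)
    for d, pv, b in zip(dmrs, p, bound):
        d.p_value = float(pv)
        d.p_is_bound = bool(b)
    return dmrs, NullResult(
        R=R,
        k=k,
        null_call_counts=null_counts,
        p_values=p,
        p_is_bound=bound,
        counting=counting,
        conservative=conservative,
    )


def detection_probability(p: float, n: int) -> float:
    """Probability that n HWE samples include both homozygous epialleles.

    P(p, q) = 1 - [(1-p^2)^n + (1-q^2)^n - (2pq)^n], q = 1 - p; this is
    the chance the caller's "one fully methylated and one unmethylated
    sample" requirement can be met. Symmetric in p and q, 0 at n = 1.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = 1.0 - p
    val = 1.0 - ((1.0 - p * p) ** n + (1.0 - q * q) ** n - (2.0 * p * q) ** n)
    return float(np.clip(val, 0.0, 1.0))


def detection_rate(
    mafs: np.ndarray, n: int, weights: np.ndarray | None = None
) -> float:
    """Weighted mean detection probability over an allele-frequency spectrum."""
    mafs = np.asarray(mafs, float)
    if mafs.size == 0:
        raise ValueError("empty allele-frequency spectrum")
    if weights is None:
        weights = np.ones_like(mafs)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    probs = np.array([detection_probability(p, n) for p in mafs])
    return float((weights * probs).sum())


def read_maf_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 1- or 2-column TSV (MAF, optional weight)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    mafs = df.iloc[:, 0].to_numpy(float)
    weights = df.iloc[:, 1].to_numpy(float) if df.shape[1] > 1 else np.ones_like(mafs)
    return mafs, weights


def extrapolate_total(n_detected: int, rate: float) -> float:
    """Estimated total DMR count = detected / detection rate (unrounded)."""
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    return n_detected / rate
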