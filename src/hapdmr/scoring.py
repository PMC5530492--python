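"""Beta-mixture epigenotype classification and SNP-DMR co-variation
scoring.

At a region with haplotype-dependent allele-specific methylation, a
sample's core methylation is expected near 0 (no methylated allele),
0.5 (one) or 1 (two), blurred by finite coverage, imprecise borders and
epigenetic mosaicism. Rather than hard thresholds, the pooled core
methylations of all called DMRs are decomposed into a three-component
beta mixture ("unmethylated", "half-methylated", "full-methylated"),
and a sample's epigenotype is soft-assigned through the posterior

    L(g, mu) = pi_g b_{alpha_g, beta_g}(mu) / sum_k pi_k b_{alpha_k, beta_k}(mu),

where b is the beta density and g in {0, 1, 2} doubles as the allele
dosage of a candidate SNP. The co-variation score of SNP s and DMR d is
the product of per-sample posteriors

    score(s, d) = prod_i L(g_i(s), mu_i(d)),

evaluated for every SNP within a +/-6 kb window around the DMR center;
scores above 0.9 (for five samples) call the SNP correlated. Because the
methylated epiallele may ride on either SNP allele, both genotype->class
orientations are evaluated by default and the better one is kept.

The mixture is fitted by expectation-maximization with an exact weighted
maximum-likelihood M-step (damped Newton on the concave per-component
beta log-likelihood), method-of-moments initialization on values
partitioned at 1/3 and 2/3, and jittered restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, polygamma

from .caller import DMR
from .io import GenotypeTable

CLASS_NAMES = ("unmethylated", "half-methylated", "full-methylated")
ORIENTATIONS = ("alt_methylated", "ref_methylated")

_EPS = 1e-6
_PARAM_LO, _PARAM_HI = 1e-3, 1e6


class DegenerateDataError(ValueError):
    """Input values cannot support a mixture fit (e.g. all identical)."""


@dataclass
class BetaMixture:
    """A fitted three-component beta mixture over [0, 1].

    Components are ordered by increasing mean; component k corresponds to
    epigenotype class k = number of methylated alleles.
    """

    pi: np.ndarray  # (k,) mixture weights
    alpha: np.ndarray  # (k,) shape parameters
    beta: np.ndarray  # (k,)
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = False
    ll_trace: list = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return self.pi.size

    def component_means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)

    def log_density(self, mu: np.ndarray) -> np.ndarray:
        """(n, k) log density of each component at each value."""
        mu = np.clip(np.asarray(mu, float), _EPS, 1 - _EPS)[..., None]
        a, b = self.alpha[None, :], self.beta[None, :]
        return (a - 1) * np.log(mu) + (b - 1) * np.log1p(-mu) - betaln(a, b)

    def posteriors(self, mu: np.ndarray) -> np.ndarray:
        """(n, k) posterior class probabilities; rows sum to 1."""
        mu = np.atleast_1d(np.asarray(mu, float))
        logp = self.log_density(mu) + np.log(self.pi)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _weighted_beta_mle(
    t1: float, t2: float, a0: float, b0: float, n_iter: int = 60, tol: float = 1e-12
) -> tuple[float, float]:
    """Maximize w-weighted beta log-likelihood given sufficient statistics
    t1 = E_w[log x], t2 = E_w[log(1-x)]; damped Newton from (a0, b0).

    The per-component log-likelihood a*t1 + b*t2 - ln B(a, b) is concave
    in (a, b), so Newton with step halving converges to the maximum.
    """

    def obj(a, b):
        return a * t1 + b * t2 - betaln(a, b)

    a, b = float(np.clip(a0, _PARAM_LO, _PARAM_HI)), float(np.clip(b0, _PARAM_LO, _PARAM_HI))
    f = obj(a, b)
    for _ in range(n_iter):
        dab = digamma(a + b)
        g1 = t1 - digamma(a) + dab
        g2 = t2 - digamma(b) + dab
        tab = polygamma(1, a + b)
        h11 = -polygamma(1, a) + tab
        h22 = -polygamma(1, b) + tab
        det = h11 * h22 - tab * tab
        if det == 0 or not np.isfinite(det):
            break
        da = -(h22 * g1 - tab * g2) / det
        db = -(h11 * g2 - tab * g1) / det
        step = 1.0
        improved = False
        for _ in range(30):
            na = np.clip(a + step * da, _PARAM_LO, _PARAM_HI)
            nb = np.clip(b + step * db, _PARAM_LO, _PARAM_HI)
            nf = obj(na, nb)
            if nf >= f:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if abs(nf - f) < tol and abs(na - a) < 1e-10 and abs(nb - b) < 1e-10:
            a, b, f = na, nb, nf
            break
        a, b, f = na, nb, nf
    return a, b


def _moments_init(values: np.ndarray, edges: tuple[float, float]) -> tuple[np.ndarray, ...]:
    """Method-of-moments per block of a two-edge partition of [0, 1]."""
    bounds = (-np.inf, *edges, np.inf)
    pis, alphas, betas = [], [], []
    for k in range(3):
        block = values[(values > bounds[k]) & (values <= bounds[k + 1])]
        if block.size < 2:
            # empty/singleton block: flat component centered on the block
            m = {0: 0.15, 1: 0.5, 2: 0.85}[k] if block.size == 0 else float(block[0])
            v = 0.04
        else:
            m = float(np.clip(block.mean(), _EPS, 1 - _EPS))
            v = float(max(block.var(), 1e-5))
        v = min(v, m * (1 - m) * 0.999)
        conc = m * (1 - m) / v - 1
        alphas.append(np.clip(m * conc, _PARAM_LO, _PARAM_HI))
        betas.append(np.clip((1 - m) * conc, _PARAM_LO, _PARAM_HI))
        pis.append(max(block.size, 0.5))
    pi = np.asarray(pis, float)
    return pi / pi.sum(), np.asarray(alphas, float), np.asarray(betas, float)


def fit_beta_mixture(
    values: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BetaMixture:
    """Fit a k=3 beta mixture to values in [0, 1] by EM.

    Values are clamped to [1e-6, 1 - 1e-6]. Requires at least 3k values.
    The log-likelihood is non-decreasing across EM iterations; the fit
    stops when its improvement falls below ``tol`` or after ``max_iter``
    iterations. Components are returned sorted by mean.
    """
    if k != 3:
        raise ValueError("only the three-class epigenotype mixture is supported")
    values = np.asarray(values, float).ravel()
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input")
    if (values < 0).any() or (values > 1).any():
        raise ValueError("values must lie in [0, 1]")
    if values.size < 3 * k:
        raise ValueError(f"need at least {3 * k} values to fit {k} components")
    values = np.clip(values, _EPS, 1 - _EPS)
    if np.ptp(values) < 1e-9:
        raise DegenerateDataError("all values identical; mixture fit is undefined")

    rng = np.random.default_rng(seed)
    logx = np.log(values)
    log1mx = np.log1p(-values)
    best: BetaMixture | None = None
    for r in range(n_restarts):
        if r == 0:
            edges = (1 / 3, 2 / 3)
        else:
            jit = rng.uniform(-0.08, 0.08, size=2)
            edges = (1 / 3 + jit[0], 2 / 3 + jit[1])
        pi, alpha, beta = _moments_init(values, edges)
        mix = BetaMixture(pi=pi, alpha=alpha, beta=beta)
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            logp = mix.log_density(values) + np.log(np.maximum(mix.pi, 1e-300))[None, :]
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            ll = float(lse.sum())
            mix.ll_trace.append(ll)
            resp = np.exp(logp - lse[:, None])
            w = resp.sum(axis=0)
            mix.pi = np.maximum(w, 1e-8) / np.maximum(w, 1e-8).sum()
            for j in range(3):
                if w[j] < 1e-6:
                    continue  # vanished component: keep previous shape
                t1 = float(resp[:, j] @ logx / w[j])
                t2 = float(resp[:, j] @ log1mx / w[j])
                mix.alpha[j], mix.beta[j] = _weighted_beta_mle(
                    t1, t2, mix.alpha[j], mix.beta[j]
                )
            mix.n_iter = it
            if ll - prev_ll < tol and it > 1:
                mix.converged = True
                mix.log_likelihood = ll
                break
            prev_ll = ll
            mix.log_likelihood = ll
        order = np.argsort(mix.component_means())
        mix.pi = mix.pi[order]
        mix.alpha = mix.alpha[order]
        mix.beta = mix.beta[order]
        if best is None or mix.log_likelihood > best.log_likelihood:
            best = mix
    assert best is not None
    means = best.component_means()
    if not (np.diff(means) > 0).all():
        warnings.warn(
            "beta-mixture components are not strictly ordered by mean; "
            "fit is degenerate (collapsed components)",
            RuntimeWarning,
        )
    return best


def posterior(mixture: BetaMixture, g: int, mu: float) -> float:
    """L(g, mu): posterior probability of epigenotype class g given mu."""
    if g not in (0, 1, 2):
        raise ValueError("g must be in {0, 1, 2}")
    return float(mixture.posteriors(np.array([mu]))[0, g])


@dataclass
class SNPDMRScore:
    """Product-of-posteriors co-variation score for one SNP-DMR pair."""

    snp_id: str
    dmr_id: str
    score: float
    orientation: str  # which allele carries methylation
    factors: np.ndarray = field(repr=False)  # per used sample
    n_samples_used: int = 0
    all_missing: bool = False


def score_snp_dmr(
    mixture: BetaMixture,
    dosages: np.ndarray,
    core_meth: np.ndarray,
    orientation_policy: str = "both",
    snp_id: str = "",
    dmr_id: str = "",
) -> SNPDMRScore:
    """Score SNP-DMR co-variation as the product of per-sample posteriors.

    ``dosages`` are alt-allele counts in {0, 1, 2} with NaN for missing;
    missing samples are omitted from the product (flagged via
    ``n_samples_used``). With ``orientation_policy="both"`` the product
    is evaluated under g -> class g (alt allele methylated) and
    g -> class 2-g (ref allele methylated) and the larger is kept.
    """
    if orientation_policy not in ("both", *ORIENTATIONS):
        raise ValueError(f"unknown orientation policy: {orientation_policy!r}")
    dosages = np.asarray(dosages, float)
    core_meth = np.asarray(core_meth, float)
    if dosages.shape != core_meth.shape:
        raise ValueError("dosages and core methylations must align sample-wise")
    used = ~np.isnan(dosages)
    if not used.any():
        return SNPDMRScore(
            snp_id=snp_id, dmr_id=dmr_id, score=np.nan,
            orientation="undefined", factors=np.array([]),
            n_samples_used=0, all_missing=True,
        )
    g = dosages[used].astype(int)
    post = mixture.posteriors(core_meth[used])
    idx = np.arange(g.size)
    candidates = []
    if orientation_policy in ("both", "alt_methylated"):
        f = post[idx, g]
        candidates.append(("alt_methylated", f))
    if orientation_policy in ("both", "ref_methylated"):
        f = post[idx, 2 - g]
        candidates.append(("ref_methylated", f))
    orientation, factors = max(candidates, key=lambda c: float(np.prod(c[1])))
    return SNPDMRScore(
        snp_id=snp_id,
        dmr_id=dmr_id,
        score=float(np.prod(factors)),
        orientation=orientation,
        factors=factors,
        n_samples_used=int(used.sum()),
    )


def scan_window(
    dmr: DMR,
    genotypes: GenotypeTable,
    mixture: BetaMixture,
    window_bp: int = 6000,
    threshold: float = 0.9,
    orientation_policy: str = "both",
) -> pd.DataFrame:
    """Score every SNP within ``window_bp`` of the DMR center.

    The window is anchored at the midpoint of the member-CpG span and is
    inclusive (a SNP exactly ``window_bp`` away is evaluated). Returns
    SNPs with score > ``threshold``, sorted by decreasing score.
    """
    mus = np.array([dmr.mu[s] for s in genotypes.samples if s in dmr.mu])
    sample_sel = [s for s in genotypes.samples if s in dmr.mu]
    if len(sample_sel) != len(dmr.mu):
        missing = sorted(set(dmr.mu) - set(genotypes.samples))
        raise ValueError(f"genotype table lacks samples: {', '.join(missing)}")
    center = dmr.center
    window = genotypes.in_window(dmr.chrom, center, window_bp)
    rows = []
    for _, snp in window.iterrows():
        dos = snp[sample_sel].to_numpy(float)
        sc = score_snp_dmr(
            mixture, dos, mus, orientation_policy,
            snp_id=str(snp["snp_id"]), dmr_id=dmr.dmr_id,
        )
        if sc.all_missing or not sc.score > threshold:
            continue
        rows.append(
            {
                "snp_id": sc.snp_id,
                "dmr_id": dmr.dmr_id,
                "chrom": dmr.chrom,
                "pos": int(snp["pos"]),
                "distance": float(abs(snp["pos"] - center)),
                "score": sc.score,
                "orientation": sc.orientation,
                "n_samples_used": sc.n_samples_used,
            }
        )
    cols = [
        "snp_id", "dmr_id", "chrom", "pos", "distance",
        "score", "orientation", "n_samples_used",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def pooled_core_methylations(dmrs: list[DMR]) -> np.ndarray:
    """All (DMR x sample) core methylation values, for mixture fitting."""
    return np.array([m for d in dmrs for m in d.mu.values()], float)
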