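import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from hapdmr.caller import DMR
from hapdmr.io import GenotypeTable
from hapdmr.scoring import (
    BetaMixture,
    DegenerateDataError,
    fit_beta_mixture,
    pooled_core_methylations,
    posterior,
    scan_window,
    score_snp_dmr,
)

TRUE_PI = np.array([0.35, 0.30, 0.35])
TRUE_AB = [(2, 18), (12, 12), (18, 2)]


def _draw_mixture(n, rng):
    comp = rng.choice(3, size=n, p=TRUE_PI)
    return np.concatenate(
        [rng.beta(*TRUE_AB[k], size=(comp == k).sum()) for k in range(3)]
    )


def _toy_mixture():
    return BetaMixture(
        pi=np.full(3, 1 / 3),
        alpha=np.array([2.0, 12.0, 18.0]),
        beta=np.array([18.0, 12.0, 2.0]),
    )


class TestFit:
    def test_recovers_component_means(self):
        rng = np.random.default_rng(0)
        values = _draw_mixture(800, rng)
        mix = fit_beta_mixture(values, seed=0)
        means = mix.component_means()
        np.testing.assert_allclose(means, [0.10, 0.50, 0.90], atol=0.05)
        assert (np.diff(means) > 0).all()

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(1)
        mix = fit_beta_mixture(_draw_mixture(200, rng), seed=1)
        trace = np.asarray(mix.ll_trace)
        assert (np.diff(trace) >= -1e-7).all()

    def test_all_identical_values_flagged(self):
        with pytest.raises(DegenerateDataError):
            fit_beta_mixture(np.full(30, 0.4))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least"):
            fit_beta_mixture(np.linspace(0.1, 0.9, 8))

    def test_non_finite_rejected(self):
        vals = np.linspace(0.1, 0.9, 12)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_beta_mixture(vals)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_beta_mixture(np.linspace(-0.2, 0.9, 12))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        values = _draw_mixture(150, rng)
        m1 = fit_beta_mixture(values, seed=7)
        m2 = fit_beta_mixture(values, seed=7)
        np.testing.assert_array_equal(m1.alpha, m2.alpha)
        np.testing.assert_array_equal(m1.pi, m2.pi)


class TestPosterior:
    def test_identical_components_uniform(self):
        mix = BetaMixture(
            pi=np.full(3, 1 / 3),
            alpha=np.array([5.0, 5.0, 5.0]),
            beta=np.array([5.0, 5.0, 5.0]),
        )
        for mu in (0.1, 0.5, 0.93):
            for g in (0, 1, 2):
                assert posterior(mix, g, mu) == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.001, 0.999))
    def test_posteriors_sum_to_one(self, mu):
        mix = _toy_mixture()
        total = sum(posterior(mix, g, mu) for g in (0, 1, 2))
        assert total == pytest.approx(1.0)

    def test_matches_direct_density_evaluation(self):
        mix = _toy_mixture()
        mu = 0.9
        dens = np.array([beta_dist.pdf(mu, a, b) for a, b in TRUE_AB])
        want = dens[2] / dens.sum()
        assert posterior(mix, 2, mu) == pytest.approx(want, rel=1e-9)

    def test_invalid_class(self):
        with pytest.raises(ValueError):
            posterior(_toy_mixture(), 3, 0.5)


class TestScore:
    def test_single_sample_equals_posterior(self):
        mix = _toy_mixture()
        sc = score_snp_dmr(mix, np.array([2.0]), np.array([0.9]),
                           orientation_policy="alt_methylated")
        assert sc.score == pytest.approx(posterior(mix, 2, 0.9))

    def test_adding_samples_never_increases_score(self):
        mix = _toy_mixture()
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=6).astype(float)
        mu = rng.uniform(0.05, 0.95, size=6)
        prev = np.inf
        for n in range(1, 7):
            sc = score_snp_dmr(mix, g[:n], mu[:n], orientation_policy="alt_methylated")
            assert sc.score <= prev + 1e-12
            prev = sc.score

    def test_orientation_both_takes_maximum(self):
        mix = _toy_mixture()
        g = np.array([0.0, 1.0, 2.0])
        mu = np.array([0.95, 0.5, 0.05])  # ref allele carries methylation
        both = score_snp_dmr(mix, g, mu, orientation_policy="both")
        fixed = score_snp_dmr(mix, g, mu, orientation_policy="alt_methylated")
        flipped = score_snp_dmr(mix, g, mu, orientation_policy="ref_methylated")
        assert both.orientation == "ref_methylated"
        assert both.score == pytest.approx(max(fixed.score, flipped.score))
        assert both.score > 0.9 > fixed.score

    def test_missing_genotypes_omitted_and_flagged(self):
        mix = _toy_mixture()
        g = np.array([2.0, np.nan, 0.0])
        mu = np.array([0.9, 0.5, 0.1])
        sc = score_snp_dmr(mix, g, mu)
        assert sc.n_samples_used == 2
        all_missing = score_snp_dmr(mix, np.array([np.nan]), np.array([0.5]))
        assert all_missing.all_missing and np.isnan(all_missing.score)

    def test_sample_order_invariance(self):
        mix = _toy_mixture()
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=5).astype(float)
        mu = rng.uniform(0, 1, size=5)
        perm = rng.permutation(5)
        a = score_snp_dmr(mix, g, mu)
        b = score_snp_dmr(mix, g[perm], mu[perm])
        assert a.score == pytest.approx(b.score)
        assert a.orientation == b.orientation

    def test_score_bounded_by_smallest_factor(self):
        mix = _toy_mixture()
        sc = score_snp_dmr(mix, np.array([0.0, 1.0, 2.0]), np.array([0.1, 0.5, 0.9]))
        assert sc.score <= sc.factors.min() + 1e-12


class TestScanWindow:
    def _setup(self, snp_positions):
        samples = ["S1", "S2", "S3", "S4", "S5"]
        dmr = DMR(
            dmr_id="d1", chrom="chr1", start=10_000, end=10_400,
            members=np.arange(5), n_cpgs=5,
            mu=dict(zip(samples, [0.05, 0.5, 0.95, 0.5, 0.05])),
        )
        rows = []
        dosages = {
            "concordant": [0.0, 1.0, 2.0, 1.0, 0.0],
            "discordant": [2.0, 0.0, 0.0, 2.0, 1.0],
        }
        for i, (name, pos) in enumerate(snp_positions):
            rows.append([name, "chr1", pos, *dosages.get(name.split("#")[0], dosages["concordant"])])
        gt = GenotypeTable(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", *samples]), samples)
        return dmr, gt

    def test_window_boundary_inclusive_at_6kb(self):
        center = (10_000 + 10_400) / 2  # 10200
        dmr, gt = self._setup(
            [("concordant#in", int(center + 5_999)), ("concordant#out", int(center + 6_001))]
        )
        hits = scan_window(dmr, gt, _toy_mixture(), threshold=-1.0)
        assert set(hits["snp_id"]) == {"concordant#in"}

    def test_empty_window(self):
        dmr, gt = self._setup([("concordant", 500_000)])
        assert len(scan_window(dmr, gt, _toy_mixture())) == 0

    def test_only_concordant_snp_passes_threshold(self):
        dmr, gt = self._setup([("concordant", 10_100), ("discordant", 10_300)])
        hits = scan_window(dmr, gt, _toy_mixture(), threshold=0.9)
        assert list(hits["snp_id"]) == ["concordant"]
        assert (hits["score"] > 0.9).all()


def test_pooled_core_methylations_collects_all_values():
    dmrs = [
        DMR("d1", "chr1", 1, 2, np.array([0]), 1, mu={"A": 0.1, "B": 0.9}),
        DMR("d2", "chr1", 5, 6, np.array([1]), 1, mu={"A": 0.5, "B": 0.4}),
    ]
    np.testing.assert_allclose(sorted(pooled_core_methylations(dmrs)), [0.1, 0.4, 0.5, 0.9])
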