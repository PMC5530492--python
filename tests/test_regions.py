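import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from conftest import build_cohort

from hapdmr.caller import call_dmrs
from hapdmr.io import RegionSet
from hapdmr.regions import (
    RegionSamplingError,
    empirical_over_under,
    enrichment_test,
    flank_profile,
    rank_sum_compare,
    sample_matched_regions,
    state_difference_partition,
)


def _landscape_cohort(dmr_level=0.1, flank_level=0.9, n_lead=20, n_dmr=5, n_tail=20):
    """Two-sample cohort with a perfect planted DMR inside flat flanks."""
    n = n_lead + n_dmr + n_tail
    a = np.full(n, flank_level)
    b = np.full(n, flank_level)
    a[n_lead:n_lead + n_dmr] = 1.0
    b[n_lead:n_lead + n_dmr] = dmr_level - dmr_level  # 0.0
    co = build_cohort([a, b], cov=10)
    return co


class TestFlankProfile:
    def test_uniform_landscape_is_intermediate(self):
        co = build_cohort([np.full(30, 0.5), np.full(30, 0.5)])
        d = call_dmrs(co)
        assert d == []
        # construct the profile for an artificial region in a flat landscape
        from hapdmr.caller import DMR

        dmr = DMR("d", "chr1", int(co.pos[13]), int(co.pos[16]),
                  members=np.arange(13, 17), n_cpgs=4)
        prof = flank_profile(dmr, co)
        assert prof.classification == "intermediate"  # ties are not lower/higher

    def test_hypermethylated_flanks_classify_lower_than_both(self):
        co = _landscape_cohort()
        dmrs = call_dmrs(co)
        assert len(dmrs) == 1
        prof = flank_profile(dmrs[0], co)
        assert prof.classification == "lower_than_both"
        assert prof.upstream == pytest.approx(0.9)
        assert prof.downstream == pytest.approx(0.9)
        assert prof.dmr_mean == pytest.approx(0.5)  # mean of levels 1.0 and 0.0

    def test_low_methylation_flanks_classify_higher_than_both(self):
        co = _landscape_cohort(flank_level=0.2)
        dmrs = call_dmrs(co)
        prof = flank_profile(dmrs[0], co)
        assert prof.classification == "higher_than_both"

    def test_near_chromosome_end_incomplete(self):
        co = _landscape_cohort(n_lead=5)  # only 5 CpGs upstream: skip 3 leaves 2
        dmrs = call_dmrs(co)
        prof = flank_profile(dmrs[0], co)
        assert prof.classification == "incomplete"
        assert np.isnan(prof.upstream)
        assert not np.isnan(prof.downstream)


class TestMatchedRegions:
    CPGS = {"chr1": np.arange(50, 100_000, 100, dtype=np.int64)}
    LENGTHS = {"chr1": 100_000}

    def test_constraints_hold_for_every_region(self):
        mask = RegionSet(pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [10_000, 50_000],
             "end": [15_000, 55_000], "label": ["repeat"] * 2}))
        sizes = np.array([400, 700, 1_000])
        regions = sample_matched_regions(
            self.CPGS, self.LENGTHS, sizes, n_sets=20, regions_per_set=10,
            seed=0, mask=mask, min_cpgs=4,
        )
        pos0 = self.CPGS["chr1"] - 1
        for _, r in regions.iterrows():
            n_cpg = np.searchsorted(pos0, r["end"]) - np.searchsorted(pos0, r["start"])
            assert n_cpg >= 4
            assert not mask.overlaps("chr1", np.array([r["start"]]), np.array([r["end"]]))[0]
        # sizes are a resample of the observed multiset
        assert set(regions["end"] - regions["start"]) <= set(sizes)
        assert (regions.groupby("set_id").size() == 10).all()

    def test_midpoints_uniform_without_mask(self):
        regions = sample_matched_regions(
            self.CPGS, self.LENGTHS, np.array([500]), n_sets=50,
            regions_per_set=20, seed=1, mask=None,
        )
        mid = (regions["start"] + regions["end"]) / 2
        u = (mid - 250) / (100_000 - 500)
        assert kstest(u, "uniform").pvalue > 1e-3

    def test_impossible_constraints_raise(self):
        mask = RegionSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100_000], "label": ["repeat"]}))
        with pytest.raises(RegionSamplingError):
            sample_matched_regions(
                self.CPGS, self.LENGTHS, np.array([500]), n_sets=2,
                regions_per_set=2, seed=0, mask=mask, max_rounds=20,
            )


class TestEnrichment:
    def test_counting_oracle(self):
        p_over, p_under = empirical_over_under(3, np.array([1, 2, 3, 4]))
        assert p_over == pytest.approx(0.25)
        assert p_under == pytest.approx(0.5)

    def test_boundary_observed_above_all(self):
        p_over, p_under = empirical_over_under(10, np.array([1, 2, 3, 4]))
        assert p_over == 0.0
        assert p_under == 1.0

    def test_identical_labels_get_identical_pvalues(self):
        cpgs = {"chr1": np.arange(50, 50_000, 100, dtype=np.int64)}
        lengths = {"chr1": 50_000}
        iv = pd.DataFrame({"chrom": ["chr1"] * 5,
                           "start": [1_000, 9_000, 21_000, 33_000, 41_000],
                           "end": [1_500, 9_600, 21_400, 33_800, 41_500]})
        ann = pd.DataFrame({
            "chrom": ["chr1"] * 4,
            "start": [0, 25_000, 0, 25_000],
            "end": [8_000, 35_000, 8_000, 35_000],
            "label": ["x", "x", "y", "y"],
        })
        results = enrichment_test(
            iv, RegionSet(ann), cpgs, lengths, n_sets=300, seed=5
        )
        by_label = {r.label: r for r in results}
        assert by_label["x"].p_over == by_label["y"].p_over
        assert by_label["x"].p_under == by_label["y"].p_under
        assert by_label["x"].observed == by_label["y"].observed


class TestStateDifference:
    IV = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})

    def _states(self, labels, start=0, end=300):
        return RegionSet(pd.DataFrame({
            "chrom": ["chr1"] * len(labels),
            "start": [start] * len(labels),
            "end": [end] * len(labels),
            "label": labels,
        }))

    def test_identical_annotations_no_difference(self):
        d, s, assign = state_difference_partition(
            self.IV, self._states(["enhancer"]), self._states(["enhancer"]),
            np.array([0.5]))
        assert d.size == 0 and s.size == 1

    def test_disjoint_labels_are_different(self):
        d, s, _ = state_difference_partition(
            self.IV, self._states(["enhancer"]), self._states(["repressed"]),
            np.array([0.5]))
        assert list(d) == [0.5] and s.size == 0

    def test_partial_overlap_counts_as_same(self):
        d, s, _ = state_difference_partition(
            self.IV, self._states(["enhancer", "transcribed"]),
            self._states(["transcribed"]), np.array([0.5]))
        assert d.size == 0 and list(s) == [0.5]

    def test_uncovered_dmr_excluded(self):
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
        d, s, assign = state_difference_partition(
            self.IV, self._states(["enhancer"]), empty, np.array([0.5]))
        assert d.size == 0 and s.size == 0
        assert list(assign["status"]) == ["excluded"]


class TestRankSum:
    def test_exact_small_sample(self):
        stat, p = rank_sum_compare(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert stat == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_large_groups(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        _, p = rank_sum_compare(x, x + rng.normal(scale=1e-12, size=300))
        assert p > 0.9

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(loc=0.7, size=35)
        _, p1 = rank_sum_compare(a, b)
        _, p2 = rank_sum_compare(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare(np.array([]), np.array([1.0]))
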