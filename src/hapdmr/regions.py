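"""Flanking-methylation profiles and annotation enrichment of DMRs.

Flank profiling
---------------
For each DMR, the three aligned CpGs on each side are skipped (border
effects) and the next ten are averaged, giving upstream/downstream flank
means to compare against the DMR's own mean methylation. Regions with
fewer than ten available flank CpGs on a side are classed ``incomplete``;
otherwise strict comparisons assign ``lower_than_both``,
``higher_than_both`` or ``intermediate``. At allele-specific regions
embedded in a hypermethylated background the expected pattern is a DMR
mean near 0.5 flanked by ~0.72 methylation on both sides.

Matched-random-region enrichment
--------------------------------
Over/under-representation of DMRs in labelled annotations (chromatin
states, gene features, CpG islands) is assessed against random region
sets matched to the observed DMRs: each set has the same number of
regions with lengths resampled from the observed size distribution,
placed uniformly among positions that avoid the repeat mask and cover at
least four CpGs. The empirical p for overrepresentation of a label is
the fraction of random sets with a *higher* overlap count than observed
(underrepresentation: lower count); ties count toward neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .caller import DMR
from .io import CohortMatrix, RegionSet

logger = logging.getLogger(__name__)

FLANK_CLASSES = ("lower_than_both", "higher_than_both", "intermediate", "incomplete")


class RegionSamplingError(RuntimeError):
    """The constraint-satisfying placement space is too small."""


@dataclass
class FlankProfile:
    """Flank vs DMR methylation summary for one region."""

    dmr_id: str
    dmr_mean: float
    upstream: float  # NaN when incomplete
    downstream: float
    n_upstream: int
    n_downstream: int
    classification: str


def flank_profile(
    dmr: DMR,
    cohort: CohortMatrix,
    skip: int = 3,
    n_flank: int = 10,
) -> FlankProfile:
    """Mean methylation of the DMR vs its upstream/downstream flanks.

    Flank means use the per-CpG cross-sample mean level (pooled over
    samples); a side is complete only when ``n_flank`` CpGs exist beyond
    the ``skip`` buffer within the same chromosome.
    """
    site_mean = cohort.level.mean(axis=0)
    a = int(dmr.members[0])
    b = int(dmr.members[-1]) + 1
    block = cohort.chrom_block(dmr.chrom)
    up_hi = a - skip
    up_lo = up_hi - n_flank
    n_up = max(0, min(up_hi, b) - max(up_lo, block.start))
    down_lo = b + skip
    down_hi = down_lo + n_flank
    n_down = max(0, min(down_hi, block.stop) - down_lo)
    upstream = float(site_mean[up_lo:up_hi].mean()) if (
        up_lo >= block.start and n_up == n_flank
    ) else np.nan
    downstream = float(site_mean[down_lo:down_hi].mean()) if (
        down_hi <= block.stop and n_down == n_flank
    ) else np.nan
    dmr_mean = float(site_mean[a:b].mean())
    if np.isnan(upstream) or np.isnan(downstream):
        cls = "incomplete"
    elif dmr_mean < upstream and dmr_mean < downstream:
        cls = "lower_than_both"
    elif dmr_mean > upstream and dmr_mean > downstream:
        cls = "higher_than_both"
    else:
        cls = "intermediate"
    return FlankProfile(
        dmr_id=dmr.dmr_id,
        dmr_mean=dmr_mean,
        upstream=upstream,
        downstream=downstream,
        n_upstream=n_up if not np.isnan(upstream) else min(n_up, n_flank),
        n_downstream=n_down,
        classification=cls,
    )


def flank_profiles_frame(
    dmrs: list[DMR], cohort: CohortMatrix, skip: int = 3, n_flank: int = 10
) -> pd.DataFrame:
    rows = [flank_profile(d, cohort, skip, n_flank).__dict__ for d in dmrs]
    return pd.DataFrame(
        rows,
        columns=[
            "dmr_id", "dmr_mean", "upstream", "downstream",
            "n_upstream", "n_downstream", "classification",
        ],
    )


def _prepare_sampling(
    cpg_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    mask: RegionSet | None,
):
    """Per-chrom 0-based CpG coordinates and merged mask intervals."""
    chroms = list(chrom_lengths)
    pos0 = {c: np.asarray(cpg_positions.get(c, np.empty(0, np.int64)), np.int64) - 1
            for c in chroms}
    masks = {}
    for c in chroms:
        if mask is None:
            masks[c] = (np.empty(0, np.int64), np.empty(0, np.int64))
        else:
            masks[c] = mask.merged_intervals(None, c)
    lengths = np.array([chrom_lengths[c] for c in chroms], float)
    return chroms, pos0, masks, lengths / lengths.sum()


def sample_matched_regions(
    cpg_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    sizes: np.ndarray,
    n_sets: int,
    regions_per_set: int,
    seed: int = 0,
    mask: RegionSet | None = None,
    min_cpgs: int = 4,
    max_rounds: int = 200,
) -> pd.DataFrame:
    """Random region sets matched to an observed size distribution.

    Returns a frame with columns ``set_id, chrom, start, end`` (0-based
    half-open). Region lengths are resampled with replacement from
    ``sizes``; placements are uniform among starts whose region avoids
    the repeat mask and covers at least ``min_cpgs`` CpGs. Raises
    :class:`RegionSamplingError` when rejection sampling cannot fill the
    request.
    """
    sizes = np.asarray(sizes, np.int64)
    if sizes.size == 0:
        raise ValueError("need at least one observed size")
    rng = np.random.default_rng(seed)
    chroms, pos0, masks, chrom_p = _prepare_sampling(cpg_positions, chrom_lengths, mask)
    total = n_sets * regions_per_set
    out_chrom = np.empty(total, object)
    out_start = np.empty(total, np.int64)
    out_size = rng.choice(sizes, size=total, replace=True)
    unfilled = np.arange(total)
    for _ in range(max_rounds):
        if unfilled.size == 0:
            break
        m = unfilled.size
        ci = rng.choice(len(chroms), size=m, p=chrom_p)
        starts = np.empty(m, np.int64)
        ok = np.ones(m, bool)
        for k, c in enumerate(chroms):
            sel = ci == k
            if not sel.any():
                continue
            L = chrom_lengths[c]
            sz = out_size[unfilled[sel]]
            fit = sz < L
            s = np.where(
                fit,
                rng.integers(0, np.maximum(L - sz, 1)),
                0,
            )
            e = s + sz
            p = pos0[c]
            n_cpg = np.searchsorted(p, e, side="left") - np.searchsorted(p, s, side="left")
            good = fit & (n_cpg >= min_cpgs)
            mstarts, mends = masks[c]
            if mstarts.size:
                idx = np.searchsorted(mends, s, side="right")
                hit = idx < mstarts.size
                masked = np.zeros(s.shape, bool)
                masked[hit] = mstarts[idx[hit]] < e[hit]
                good &= ~masked
            starts[sel] = s
            ok[sel] &= good
        accepted = unfilled[ok]
        out_start[accepted] = starts[ok]
        out_chrom[accepted] = np.asarray(chroms, object)[ci[ok]]
        unfilled = unfilled[~ok]
    if unfilled.size:
        raise RegionSamplingError(
            f"could not place {unfilled.size}/{total} regions after {max_rounds} "
            "rounds; constraints (mask, min CpGs) leave too little space"
        )
    return pd.DataFrame(
        {
            "set_id": np.repeat(np.arange(n_sets), regions_per_set),
            "chrom": out_chrom,
            "start": out_start,
            "end": out_start + out_size,
        }
    )


def _overlap_counts_per_set(
    regions: pd.DataFrame, annotation: RegionSet, label: str, n_sets: int
) -> np.ndarray:
    """Number of regions per set overlapping >=1 bp of the label."""
    counts = np.zeros(n_sets, np.int64)
    for chrom, sub in regions.groupby("chrom", sort=False):
        hit = annotation.overlaps(
            str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy(), label
        )
        np.add.at(counts, sub["set_id"].to_numpy()[hit], 1)
    return counts


def empirical_over_under(observed: int, null_counts: np.ndarray) -> tuple[float, float]:
    """(p_over, p_under): fractions of null sets with strictly higher /
    strictly lower counts than observed; ties count toward neither."""
    null_counts = np.asarray(null_counts)
    return float((null_counts > observed).mean()), float((null_counts < observed).mean())


@dataclass
class EnrichmentResult:
    """Empirical over/under-representation for one annotation label."""

    label: str
    observed: int
    null_mean: float
    null_sd: float
    p_over: float
    p_under: float


def enrichment_test(
    dmr_intervals: pd.DataFrame,
    annotation: RegionSet,
    cpg_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    n_sets: int = 10_000,
    regions_per_set: int | None = None,
    seed: int = 0,
    mask: RegionSet | None = None,
    min_cpgs: int = 4,
    labels: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Empirical enrichment of DMRs in each annotation label.

    ``dmr_intervals`` needs columns ``chrom, start, end`` (0-based
    half-open). p_over is the fraction of matched random sets with a
    strictly higher overlap count than observed; p_under with strictly
    lower. The number of regions per random set defaults to the number
    of observed DMRs.
    """
    if n_sets < 100:
        logger.warning("n_sets=%d gives coarse empirical p resolution", n_sets)
    if len(dmr_intervals) == 0:
        raise ValueError("no DMR intervals supplied")
    sizes = (dmr_intervals["end"] - dmr_intervals["start"]).to_numpy(np.int64)
    regions_per_set = regions_per_set or len(dmr_intervals)
    random_sets = sample_matched_regions(
        cpg_positions, chrom_lengths, sizes, n_sets, regions_per_set,
        seed=seed, mask=mask, min_cpgs=min_cpgs,
    )
    obs = dmr_intervals.assign(set_id=0)
    results = []
    for label in labels if labels is not None else annotation.labels:
        observed = int(_overlap_counts_per_set(obs, annotation, label, 1)[0])
        null = _overlap_counts_per_set(random_sets, annotation, label, n_sets)
        p_over, p_under = empirical_over_under(observed, null)
        results.append(
            EnrichmentResult(
                label=label,
                observed=observed,
                null_mean=float(null.mean()),
                null_sd=float(null.std()),
                p_over=p_over,
                p_under=p_under,
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def state_difference_partition(
    dmr_intervals: pd.DataFrame,
    states_a: RegionSet,
    states_b: RegionSet,
    meth_diffs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Split |methylation difference| by chromatin-state concordance.

    A DMR has a *different* state in the two donors iff the sets of state
    labels overlapping it are disjoint. Returns (diffs_different,
    diffs_same, assignment frame); DMRs overlapping no state in one
    donor are excluded with a warning.
    """
    meth_diffs = np.asarray(meth_diffs, float)
    if len(dmr_intervals) != meth_diffs.size:
        raise ValueError("one methylation difference per DMR required")
    rows = []
    for i, (_, r) in enumerate(dmr_intervals.iterrows()):
        la = states_a.labels_overlapping(r["chrom"], int(r["start"]), int(r["end"]))
        lb = states_b.labels_overlapping(r["chrom"], int(r["start"]), int(r["end"]))
        if not la or not lb:
            logger.warning(
                "DMR %s:%d-%d overlaps no chromatin state in one donor; excluded",
                r["chrom"], r["start"], r["end"],
            )
            status = "excluded"
        else:
            status = "different" if la.isdisjoint(lb) else "same"
        rows.append({"chrom": r["chrom"], "start": r["start"], "end": r["end"],
                     "status": status, "meth_diff": meth_diffs[i]})
    assign = pd.DataFrame(rows)
    diffs_different = assign.loc[assign["status"] == "different", "meth_diff"].to_numpy()
    diffs_same = assign.loc[assign["status"] == "same", "meth_diff"].to_numpy()
    return diffs_different, diffs_same, assign


def rank_sum_compare(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) two-sided comparison.

    Uses the exact null distribution for combined sizes up to 20 without
    ties and the tie-corrected normal approximation otherwise. Returns
    (U statistic of the first group, two-sided p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
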