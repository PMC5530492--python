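"""Extreme-methylome DMR discovery.

From an aligned cohort, two synthetic extreme methylomes are formed: one
taking the highest methylation level of each CpG across samples, one the
lowest. The per-CpG statistic is their difference

    t(c) = max(c) - min(c),

and candidate regions are maximal runs of consecutive aligned CpGs with
t(c) > v (default v = 0.5), broken at chromosome changes and at gaps
larger than ``max_gap``. A candidate becomes a DMR when it has at least
``min_cpgs`` member CpGs and the sigma-weighted core methylation of the
max envelope exceeds that of the min envelope by at least
``min_core_diff`` (default 0.8 — a difference that implies at least one
individual is homozygously methylated and another homozygously
unmethylated across the region).

The core methylation of region d in sample i is the sigma-weighted
average of the member-CpG levels,

    mu_i(d) = sum_c sigma(c) m_i(c) / sum_c sigma(c),

which down-weights low-variance border CpGs and is therefore robust to
imprecise region borders. The normalization by the sigma sum keeps mu in
[0, 1] (a convex combination), which the downstream beta-mixture stage
requires; ``core_normalization="printed"`` divides by the member count
instead, for compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortMatrix, compute_sigma

CORE_NORMALIZATIONS = ("sigma_sum", "printed")


@dataclass
class CallerParams:
    """Thresholds controlling DMR calling."""

    v: float = 0.5
    min_cpgs: int = 4
    min_core_diff: float = 0.8
    max_gap: int = 300
    core_normalization: str = "sigma_sum"
    smooth_width_bp: int | None = None  # None = smoothing off

    def __post_init__(self) -> None:
        if not 0 < self.v < 1:
            raise ValueError("v must be in (0, 1)")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")
        if not 0 < self.min_core_diff <= 1:
            raise ValueError("min_core_diff must be in (0, 1]")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.core_normalization not in CORE_NORMALIZATIONS:
            raise ValueError(f"core_normalization must be one of {CORE_NORMALIZATIONS}")
        if self.smooth_width_bp is not None and self.smooth_width_bp <= 0:
            raise ValueError("smooth_width_bp must be positive")


@dataclass
class ExtremeEnvelope:
    """Per-site extreme levels and their difference t(c)."""

    chrom: np.ndarray
    chrom_id: np.ndarray
    pos: np.ndarray
    vmax: np.ndarray
    vmin: np.ndarray
    t: np.ndarray
    sigma: np.ndarray


@dataclass
class DMR:
    """A called differentially methylated region.

    ``start``/``end`` are the 1-based positions of the first and last
    member CpG; ``members`` indexes the aligned cohort's site arrays.
    """

    dmr_id: str
    chrom: str
    start: int
    end: int
    members: np.ndarray = field(repr=False)
    n_cpgs: int = 0
    core_max: float = 0.0
    core_min: float = 0.0
    envelope_diff: float = 0.0
    mu: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None
    p_is_bound: bool = False

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


def build_envelope(cohort: CohortMatrix) -> ExtremeEnvelope:
    """Elementwise max/min methylation level over samples per site."""
    vmax = cohort.level.max(axis=0)
    vmin = cohort.level.min(axis=0)
    return ExtremeEnvelope(
        chrom=cohort.chrom,
        chrom_id=cohort.chrom_id,
        pos=cohort.pos,
        vmax=vmax,
        vmin=vmin,
        t=vmax - vmin,
        sigma=cohort.sigma,
    )


def _runs(
    t: np.ndarray,
    pos: np.ndarray,
    chrom_id: np.ndarray,
    v: float,
    max_gap: int,
) -> list[tuple[int, int]]:
    """Maximal runs [a, b) of consecutive sites with t > v."""
    idx = np.flatnonzero(t > v)
    if idx.size == 0:
        return []
    brk = (
        (idx[1:] != idx[:-1] + 1)
        | (chrom_id[idx[1:]] != chrom_id[idx[:-1]])
        | (pos[idx[1:]] - pos[idx[:-1]] > max_gap)
    )
    starts = np.concatenate(([0], np.flatnonzero(brk) + 1))
    ends = np.concatenate((np.flatnonzero(brk) + 1, [idx.size]))
    return [(int(idx[a]), int(idx[b - 1]) + 1) for a, b in zip(starts, ends)]


def segment(envelope: ExtremeEnvelope, params: CallerParams) -> list[tuple[int, int]]:
    """Candidate regions as half-open site-index ranges (no size/diff filter)."""
    return _runs(envelope.t, envelope.pos, envelope.chrom_id, params.v, params.max_gap)


def core_methylation(
    levels: np.ndarray, sigma: np.ndarray, normalization: str = "sigma_sum"
) -> float:
    """Sigma-weighted average methylation of a region's member CpGs.

    Falls back to the unweighted mean when all weights are zero.
    """
    levels = np.asarray(levels, float)
    sigma = np.asarray(sigma, float)
    if levels.size == 0:
        raise ValueError("empty region")
    ssum = sigma.sum()
    if ssum == 0:
        return float(levels.mean())
    if normalization == "printed":
        return float((sigma * levels).sum() / levels.size)
    return float((sigma * levels).sum() / ssum)


def _qualifying_runs(
    level: np.ndarray,
    pos: np.ndarray,
    chrom_id: np.ndarray,
    params: CallerParams,
    sigma: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Site-index ranges passing all caller filters. Fast path shared with
    the empirical-null machinery (which calls it thousands of times)."""
    if sigma is None:
        sigma = compute_sigma(level)
    vmax = level.max(axis=0)
    vmin = level.min(axis=0)
    t = vmax - vmin
    runs = _runs(t, pos, chrom_id, params.v, params.max_gap)
    if not runs:
        return []
    cs = np.concatenate(([0.0], np.cumsum(sigma)))
    cst = np.concatenate(([0.0], np.cumsum(sigma * t)))
    out = []
    for a, b in runs:
        if b - a < params.min_cpgs:
            continue
        ssum = cs[b] - cs[a]
        wsum = cst[b] - cst[a]
        if ssum == 0:
            diff = float(t[a:b].mean())
        elif params.core_normalization == "printed":
            diff = float(wsum / (b - a))
        else:
            diff = float(wsum / ssum)
        if diff >= params.min_core_diff:
            out.append((a, b))
    return out


def call_dmrs(cohort: CohortMatrix, params: CallerParams | None = None) -> list[DMR]:
    """Run the full extreme-methylome caller on an aligned cohort."""
    params = params or CallerParams()
    level = cohort.level
    if params.smooth_width_bp is not None:
        level = _smooth_levels(
            level, cohort.cov, cohort.pos, cohort.chrom_id, params.smooth_width_bp
        )
    runs = _qualifying_runs(level, cohort.pos, cohort.chrom_id, params, sigma=None)
    sigma = compute_sigma(level)
    vmax = level.max(axis=0)
    vmin = level.min(axis=0)
    dmrs = []
    for k, (a, b) in enumerate(runs):
        sl = slice(a, b)
        norm = params.core_normalization
        core_max = core_methylation(vmax[sl], sigma[sl], norm)
        core_min = core_methylation(vmin[sl], sigma[sl], norm)
        mu = {
            s: core_methylation(level[i, sl], sigma[sl], norm)
            for i, s in enumerate(cohort.samples)
        }
        dmrs.append(
            DMR(
                dmr_id=f"dmr{k + 1}",
                chrom=str(cohort.chrom[a]),
                start=int(cohort.pos[a]),
                end=int(cohort.pos[b - 1]),
                members=np.arange(a, b),
                n_cpgs=b - a,
                core_max=core_max,
                core_min=core_min,
                envelope_diff=core_max - core_min,
                mu=mu,
            )
        )
    return dmrs


def _smooth_levels(
    level: np.ndarray,
    cov: np.ndarray,
    pos: np.ndarray,
    chrom_id: np.ndarray,
    width_bp: int,
) -> np.ndarray:
    """Coverage-weighted boxcar average of levels over centered bp windows."""
    out = np.empty_like(level)
    half = width_bp / 2.0
    for cid in np.unique(chrom_id):
        sl = np.flatnonzero(chrom_id == cid)
        p = pos[sl]
        lo = np.searchsorted(p, p - half, side="left")
        hi = np.searchsorted(p, p + half, side="right")
        w = cov[:, sl].astype(float)
        cw = np.concatenate((np.zeros((w.shape[0], 1)), np.cumsum(w, axis=1)), axis=1)
        cwl = np.concatenate(
            (np.zeros((w.shape[0], 1)), np.cumsum(w * level[:, sl], axis=1)), axis=1
        )
        denom = cw[:, hi] - cw[:, lo]
        numer = cwl[:, hi] - cwl[:, lo]
        out[:, sl] = np.where(denom > 0, numer / np.maximum(denom, 1e-300), level[:, sl])
    return out


def smooth(methylome: pd.DataFrame, width_bp: int) -> pd.DataFrame:
    """Smooth a single methylome's levels (counts untouched)."""
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    from .io import sort_chroms

    df = methylome.copy()
    names = sort_chroms(df["chrom"])
    code = {c: i for i, c in enumerate(names)}
    chrom_id = df["chrom"].map(code).to_numpy(np.int64)
    level = df["level"].to_numpy(float)[None, :]
    cov = df["cov"].to_numpy(np.int64)[None, :]
    pos = df["pos"].to_numpy(np.int64)
    df["level"] = _smooth_levels(level, cov, pos, chrom_id, width_bp)[0]
    return df


def dmrs_to_frame(dmrs: list[DMR], samples: list[str] | None = None) -> pd.DataFrame:
    """Tabulate called DMRs (one mu column per sample)."""
    if samples is None:
        samples = list(dmrs[0].mu) if dmrs else []
    rows = []
    for d in dmrs:
        row = {
            "dmr_id": d.dmr_id,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "n_cpgs": d.n_cpgs,
            "envelope_diff": d.envelope_diff,
            "p_value": d.p_value,
            "p_is_bound": d.p_is_bound,
        }
        for s in samples:
            row[f"mu_{s}"] = d.mu.get(s)
        rows.append(row)
    cols = [
        "dmr_id", "chrom", "start", "end", "n_cpgs", "envelope_diff",
        "p_value", "p_is_bound", *[f"mu_{s}" for s in samples],
    ]
    return pd.DataFrame(rows, columns=cols)


def write_dmrs_bed(dmrs: list[DMR], path, samples: list[str] | None = None) -> None:
    """BED6+ export: chrom, start0, end, id, envelope_diff, '.', mu..., p."""
    if samples is None:
        samples = list(dmrs[0].mu) if dmrs else []
    with open(path, "w") as fh:
        for d in dmrs:
            mus = "\t".join(f"{d.mu[s]:.6g}" for s in samples)
            p = "NA" if d.p_value is None else (
                f"<{d.p_value:.6g}" if d.p_is_bound else f"{d.p_value:.6g}"
            )
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.dmr_id}\t"
                f"{d.envelope_diff:.6g}\t.\t{mus}\t{p}\n"
            )
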