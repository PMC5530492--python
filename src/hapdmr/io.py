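"""Reading, writing and aligning per-CpG methylation data.

A *methylome* is a :class:`pandas.DataFrame` with columns
``chrom, pos, meth, cov, level`` where ``pos`` is the 1-based position of
the C of a CpG on the forward strand (counts from the reverse-strand G are
merged onto this position), ``meth``/``cov`` are methylated/total read
counts and ``level = meth/cov`` (NaN when ``cov == 0``).

Two on-disk dialects are supported:

``bismark_cov``
    chrom, start (1-based), end, methylation percentage, count methylated,
    count unmethylated (tab-separated; the Bismark coverage format).
``bedgraph_counts``
    chrom, start (0-based), end, level, meth, cov.

Multiple methylomes are aligned into a :class:`CohortMatrix` over the
intersection of CpGs covered at ``min_cov`` or more reads in *every*
sample, together with the per-site cross-sample standard deviation
:math:`\\sigma(c)` used downstream as the core-methylation weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METHYLOME_COLUMNS = ["chrom", "pos", "meth", "cov", "level"]

_DOSAGE_VALUES = {0, 1, 2}


class MethylomeParseError(ValueError):
    """A methylome file line could not be parsed or validated."""


class AlignmentError(ValueError):
    """Cohort alignment produced no usable CpG sites."""


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key so that chr2 < chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def sort_chroms(chroms: Iterable[str]) -> list[str]:
    return sorted(set(chroms), key=_chrom_key)


def _finalize_methylome(df: pd.DataFrame) -> pd.DataFrame:
    """Sort, merge duplicate positions (strand merge) and add levels."""
    if len(df) == 0:
        return pd.DataFrame(columns=METHYLOME_COLUMNS).astype(
            {"chrom": str, "pos": np.int64, "meth": np.int64, "cov": np.int64, "level": float}
        )
    df = df.groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "cov"]].sum()
    df["__key"] = df["chrom"].map(lambda c: _chrom_key(c))
    df = df.sort_values(["__key", "pos"], kind="mergesort").drop(columns="__key")
    df = df.reset_index(drop=True)
    bad = df["meth"] > df["cov"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise MethylomeParseError(
            f"methylated count exceeds coverage at {df.loc[i, 'chrom']}:{df.loc[i, 'pos']}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        level = df["meth"].to_numpy(float) / df["cov"].to_numpy(float)
    df["level"] = np.where(df["cov"].to_numpy() > 0, level, np.nan)
    return df[METHYLOME_COLUMNS]


def make_methylome(
    chrom: Sequence[str], pos: Sequence[int], meth: Sequence[int], cov: Sequence[int]
) -> pd.DataFrame:
    """Build a validated methylome frame from parallel arrays."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "meth": np.asarray(meth, dtype=np.int64),
            "cov": np.asarray(cov, dtype=np.int64),
        }
    )
    if (df["meth"] < 0).any() or (df["cov"] < 0).any():
        raise MethylomeParseError("negative counts are not allowed")
    return _finalize_methylome(df)


def read_methylome(path: str | Path, format: str = "bismark_cov") -> pd.DataFrame:
    """Read a per-CpG methylation table.

    Records are returned sorted by (chrom, pos) with duplicate positions
    (e.g. the two strands of a CpG) merged by summing counts.
    """
    if format not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown methylome format: {format!r}")
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    covs: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if format == "bismark_cov":
                    chrom, start, _end, _pct, cm, cu = fields[:6]
                    pos = int(start)
                    meth = int(cm)
                    cov = meth + int(cu)
                else:
                    chrom, start, _end, _level, cm, cov_s = fields[:6]
                    pos = int(start) + 1
                    meth = int(cm)
                    cov = int(cov_s)
            except (ValueError, IndexError) as exc:
                raise MethylomeParseError(f"{path}: line {lineno}: {exc}") from exc
            if meth < 0 or cov < 0:
                raise MethylomeParseError(f"{path}: line {lineno}: negative count")
            if meth > cov:
                raise MethylomeParseError(
                    f"{path}: line {lineno}: meth ({meth}) > cov ({cov})"
                )
            chroms.append(chrom)
            poss.append(pos)
            meths.append(meth)
            covs.append(cov)
    return make_methylome(chroms, poss, meths, covs)


def write_methylome(methylome: pd.DataFrame, path: str | Path, format: str = "bismark_cov") -> None:
    """Write a methylome; output is re-readable by :func:`read_methylome`.

    Records are canonicalized (sorted, duplicates merged) before writing.
    Sites with ``cov == 0`` are written with an ``NA`` level/percentage.
    """
    if format not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown methylome format: {format!r}")
    df = _finalize_methylome(methylome[["chrom", "pos", "meth", "cov"]].copy())
    with open(path, "w") as fh:
        for chrom, pos, meth, cov, level in df.itertuples(index=False):
            if format == "bismark_cov":
                pct = "NA" if cov == 0 else f"{100.0 * meth / cov:.6g}"
                fh.write(f"{chrom}\t{pos}\t{pos}\t{pct}\t{meth}\t{cov - meth}\n")
            else:
                lev = "NA" if cov == 0 else f"{meth / cov:.6g}"
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{lev}\t{meth}\t{cov}\n")


@dataclass
class GenotypeTable:
    """SNP positions with per-sample allele dosages.

    ``table`` has columns ``snp_id, chrom, pos`` followed by one float
    column per sample holding dosages in {0, 1, 2} with NaN for missing.
    """

    table: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        vals = self.table[self.samples].to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0])
        if not ok.all():
            bad = vals[~ok][0]
            raise ValueError(f"invalid dosage value {bad!r}; allowed: 0, 1, 2 or missing")
        self.table = self.table.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def dosages(self, snp_id: str) -> np.ndarray:
        row = self.table.loc[self.table["snp_id"] == snp_id, self.samples]
        if len(row) == 0:
            raise KeyError(snp_id)
        return row.to_numpy(float)[0]

    def in_window(self, chrom: str, center: float, window_bp: int) -> pd.DataFrame:
        t = self.table
        sel = (t["chrom"] == chrom) & ((t["pos"] - center).abs() <= window_bp)
        return t.loc[sel]

    def check_samples(self, cohort_samples: Sequence[str]) -> None:
        missing = [s for s in cohort_samples if s not in self.samples]
        if missing:
            raise ValueError(f"genotype table lacks samples: {', '.join(missing)}")


def read_genotypes(
    path: str | Path, format: str = "vcf_minimal", samples: Sequence[str] | None = None
) -> GenotypeTable:
    """Read a genotype table from a minimal VCF or a TSV dosage matrix.

    Only biallelic sites are kept; multiallelic sites are skipped with a
    logged warning. ``samples``, when given, is checked against the file.
    """
    if format == "vcf_minimal":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        file_samples = list(vcf.samples)
        rows = []
        n_multi = 0
        for i, var in enumerate(vcf):
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = var.gt_types
            dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            rows.append([snp_id, var.CHROM, var.POS, *dos])
        if n_multi:
            logger.warning("skipped %d multiallelic site(s) in %s", n_multi, path)
        df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", *file_samples])
        gt_table = GenotypeTable(df, file_samples)
    elif format == "tsv_dosage":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
        file_samples = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
        gt_table = GenotypeTable(df, file_samples)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if samples is not None:
        gt_table.check_samples(samples)
    return gt_table


def write_genotypes_tsv(gt: GenotypeTable, path: str | Path) -> None:
    gt.table.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open.

    Carrier for BED annotations (chromatin states, gene features, CpG
    islands, repeat masks). Intervals of one label on one chromosome are
    merged on demand for fast vectorized overlap queries.
    """

    df: pd.DataFrame  # columns: chrom, start, end, label
    _merged: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.df
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("region start must be < end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def merged_intervals(self, label: str | None, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted, merged (starts, ends) for one label (None = all) on one chrom."""
        key = (label, chrom)
        if key not in self._merged:
            df = self.df
            sel = df["chrom"] == chrom
            if label is not None:
                sel &= df["label"] == label
            sub = df.loc[sel, ["start", "end"]].sort_values("start").to_numpy(np.int64)
            starts, ends = [], []
            for s, e in sub:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[key] = (np.asarray(starts, np.int64), np.asarray(ends, np.int64))
        return self._merged[key]

    def overlaps(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, label: str | None = None
    ) -> np.ndarray:
        """Boolean array: does each query interval intersect ≥1 bp of the set?"""
        istarts, iends = self.merged_intervals(label, chrom)
        starts = np.asarray(starts, np.int64)
        ends = np.asarray(ends, np.int64)
        if istarts.size == 0:
            return np.zeros(starts.shape, bool)
        # first merged interval ending after the query start
        idx = np.searchsorted(iends, starts, side="right")
        hit = idx < istarts.size
        out = np.zeros(starts.shape, bool)
        out[hit] = istarts[idx[hit]] < ends[hit]
        return out

    def labels_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        sel = (
            (self.df["chrom"] == chrom)
            & (self.df["start"] < end)
            & (self.df["end"] > start)
        )
        return set(self.df.loc[sel, "label"])


def read_bed(path: str | Path, default_label: str = "region") -> RegionSet:
    """Read BED3/BED4 into a RegionSet (column 4 = label when present)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            label = fields[3] if len(fields) > 3 else default_label
            rows.append((chrom, start, end, label))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_bed(regions: RegionSet, path: str | Path) -> None:
    regions.df.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class CohortMatrix:
    """Aligned per-CpG methylation counts and levels across samples.

    Sites are the intersection of CpGs with ``cov >= min_cov`` in every
    sample, ordered genomically. ``sigma`` is the cross-sample standard
    deviation of the level at each site (population form by default so it
    stays defined and bounded for two samples).
    """

    samples: list[str]
    chrom: np.ndarray  # (C,) str per site
    chrom_id: np.ndarray  # (C,) int codes, genomically ordered
    pos: np.ndarray  # (C,) int64, 1-based
    meth: np.ndarray  # (S, C) int64
    cov: np.ndarray  # (S, C) int64
    level: np.ndarray  # (S, C) float
    sigma: np.ndarray  # (C,) float

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_block(self, chrom: str) -> slice:
        """Contiguous site-index slice of one chromosome."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def site_lookup(self) -> dict[tuple[str, int], int]:
        return {(c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))}


def compute_sigma(level: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Cross-sample standard deviation per site; exactly 0 for equal levels."""
    return np.asarray(level, float).std(axis=0, ddof=ddof)


def align_cohort(
    methylomes: Mapping[str, pd.DataFrame],
    min_cov: int = 3,
    sigma_ddof: int = 0,
) -> CohortMatrix:
    """Align methylomes into a :class:`CohortMatrix`.

    Sites covered below ``min_cov`` in any sample are dropped, not
    imputed: the extreme-methylome statistic needs a defined level in
    every sample at every site.
    """
    if len(methylomes) == 0:
        raise ValueError("need at least one methylome")
    samples = list(methylomes)
    indexed = {}
    common: pd.Index | None = None
    for s in samples:
        df = methylomes[s]
        keep = df.loc[df["cov"] >= min_cov]
        ix = pd.MultiIndex.from_arrays([keep["chrom"], keep["pos"]])
        indexed[s] = keep.set_index(ix)
        common = ix if common is None else common.intersection(ix)
    if common is None or len(common) == 0:
        raise AlignmentError(
            f"no CpG site has coverage >= {min_cov} in all {len(samples)} samples; "
            "consider lowering min_cov"
        )
    order = sorted(range(len(common)), key=lambda i: (_chrom_key(common[i][0]), common[i][1]))
    common = common[order]
    chrom = np.asarray([c for c, _ in common], dtype=object)
    pos = np.asarray([p for _, p in common], dtype=np.int64)
    meth = np.empty((len(samples), len(common)), np.int64)
    cov = np.empty_like(meth)
    for i, s in enumerate(samples):
        sub = indexed[s].loc[common]
        meth[i] = sub["meth"].to_numpy()
        cov[i] = sub["cov"].to_numpy()
    level = meth / cov
    names = sort_chroms(chrom)
    code = {c: i for i, c in enumerate(names)}
    chrom_id = np.asarray([code[c] for c in chrom], np.int64)
    return CohortMatrix(
        samples=samples,
        chrom=chrom,
        chrom_id=chrom_id,
        pos=pos,
        meth=meth,
        cov=cov,
        level=level,
        sigma=compute_sigma(level, ddof=sigma_ddof),
    )
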