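"""Synthetic WGBS cohorts with planted haplotype-dependent
allele-specific methylation.

The generator emulates the study conditions the package targets: a small
cohort (five male monocyte methylomes) sequenced to moderate coverage,
with a hypermethylated background and a handful of discrete regions
where methylation tracks the genotype of a nearby SNP.

Model
-----
* CpG positions per chromosome with exponential inter-CpG gaps
  (mean 100 bp by default).
* A per-CpG background methylation probability drawn once per site from
  Beta(a, b) with mean 0.72 (the hypermethylated flank level); the same
  probability applies to every sample, so background sites carry no
  inter-individual signal and any background call is a false positive.
* Planted DMRs: runs of 4-20 consecutive CpGs whose internal gaps stay
  below the caller's within-region gap bound (coherent CpG blocks, as in
  real regulatory elements), each with a causal biallelic SNP within
  +/-2 kb of the region center. Sample genotypes are Hardy-Weinberg
  draws at the configured allele frequency; each sequencing read picks
  one of the two alleles with probability 1/2 and is methylated with
  probability m_hi (methylated epiallele) or m_lo (unmethylated), each
  flipped with the mosaicism probability. Marginally the methylation
  count is binomial given the genotype.
* Coverage per site and sample is Poisson (mean 30) truncated to >= 1.
* Annotation tracks (repeat mask, chromatin states, gene features) tile
  each chromosome so the enrichment machinery has realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import GenotypeTable, RegionSet, make_methylome

CHROMATIN_STATES = ("TssA", "TssFlnk", "Tx", "Enh", "EnhWk", "ReprPC", "ReprPCWk", "Quies")
_STATE_PROBS = (0.03, 0.05, 0.12, 0.06, 0.08, 0.06, 0.10, 0.50)


class GenomeError(ValueError):
    """The requested landscape cannot be generated (e.g. chromosome too short)."""


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults mirror the study design."""

    n_samples: int = 5
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    cpg_spacing: float = 100.0  # mean exponential inter-CpG gap, bp
    coverage_lambda: float = 30.0  # Poisson mean, truncated >= 1
    bg_mean: float = 0.72  # background (flank) methylation mean
    bg_concentration: float = 10.0  # a+b of the background beta
    n_planted_dmrs: int = 10
    dmr_width_cpgs: tuple[int, int] = (4, 20)
    maf: float = 0.5  # causal-SNP allele frequency (HWE)
    m_hi: float = 0.95  # methylated epiallele per-read probability
    m_lo: float = 0.05  # unmethylated epiallele per-read probability
    mosaicism: float = 0.0  # per-read epiallele flip probability
    snp_max_offset: int = 2000  # causal SNP within this bp of DMR center
    dmr_max_internal_gap: int = 280  # planted members form one coherent block
    min_dmr_separation_cpgs: int = 30
    n_background_snps: int = 100
    repeat_fraction: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("bg_mean", "maf", "m_hi", "m_lo", "mosaicism", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_lambda <= 0:
            raise ValueError("coverage_lambda must be positive")
        if self.cpg_spacing <= 0:
            raise ValueError("cpg_spacing must be positive")
        if self.n_planted_dmrs < 0:
            raise ValueError("n_planted_dmrs must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.dmr_width_cpgs
        if not 2 <= lo <= hi:
            raise ValueError("dmr_width_cpgs must satisfy 2 <= lo <= hi")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "dmr_width_cpgs" in d:
            d["dmr_width_cpgs"] = tuple(d["dmr_width_cpgs"])
        return cls(**d)

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class PlantedDMR:
    """Ground truth for one planted allele-specific region."""

    dmr_id: str
    chrom: str
    start: int  # 1-based first member CpG
    end: int  # 1-based last member CpG
    member_pos: np.ndarray = field(repr=False)
    snp_id: str = ""
    snp_pos: int = 0
    alt_is_methylated: bool = True

    @property
    def n_cpgs(self) -> int:
        return self.member_pos.size

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Genome:
    """A simulated CpG landscape with planted regions and annotations."""

    chrom_lengths: dict[str, int]
    cpg_pos: dict[str, np.ndarray]  # 1-based, strictly increasing
    bg_level: dict[str, np.ndarray]  # per-CpG background methylation prob
    planted: list[PlantedDMR]
    repeat_mask: RegionSet
    chromatin_states: RegionSet
    gene_features: RegionSet

    @property
    def n_cpgs(self) -> int:
        return sum(p.size for p in self.cpg_pos.values())


def _tile(rng: np.random.Generator, length: int, mean_len: float,
          labels: tuple[str, ...], probs: tuple[float, ...] | None, chrom: str) -> list[tuple]:
    rows, start = [], 0
    while start < length:
        seg = max(200, int(rng.exponential(mean_len)))
        end = min(start + seg, length)
        label = labels[rng.choice(len(labels), p=probs)] if probs else labels[
            rng.integers(len(labels))]
        rows.append((chrom, start, end, label))
        start = end
    return rows


def _gene_tile(rng: np.random.Generator, length: int, chrom: str) -> list[tuple]:
    rows, start = [], 0
    while start < length:
        inter = min(start + max(500, int(rng.exponential(10_000))), length)
        rows.append((chrom, start, inter, "intergenic"))
        start = inter
        if start >= length:
            break
        gene_end = min(start + max(1000, int(rng.exponential(20_000))), length)
        exonic = True
        while start < gene_end:
            seg = max(100, int(rng.exponential(300 if exonic else 3000)))
            end = min(start + seg, gene_end)
            rows.append((chrom, start, end, "exon" if exonic else "intron"))
            exonic = not exonic
            start = end
    return rows


def simulate_genome(params: SimulationParams, seed: int | None = None) -> Genome:
    """Generate the CpG landscape, planted regions and annotation tracks.

    Deterministic given the seed (``seed`` overrides ``params.seed``).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cpg_pos: dict[str, np.ndarray] = {}
    bg_level: dict[str, np.ndarray] = {}
    ann_rows: list[tuple] = []
    gene_rows: list[tuple] = []
    a_bg = params.bg_mean * params.bg_concentration
    b_bg = (1 - params.bg_mean) * params.bg_concentration
    for chrom, length in params.chrom_lengths.items():
        n_draw = int(1.4 * length / params.cpg_spacing) + 64
        gaps = rng.exponential(params.cpg_spacing, size=n_draw)
        pos = np.unique(np.round(1 + np.cumsum(gaps)).astype(np.int64))
        pos = pos[(pos >= 1) & (pos <= length)]
        cpg_pos[chrom] = pos
        bg_level[chrom] = rng.beta(a_bg, b_bg, size=pos.size)
        ann_rows += _tile(rng, length, 2000.0, CHROMATIN_STATES, _STATE_PROBS, chrom)
        gene_rows += _gene_tile(rng, length, chrom)

    planted = _plant_dmrs(params, rng, cpg_pos)
    repeat_rows = _repeat_mask(params, rng, planted)
    return Genome(
        chrom_lengths=dict(params.chrom_lengths),
        cpg_pos=cpg_pos,
        bg_level=bg_level,
        planted=planted,
        repeat_mask=RegionSet(pd.DataFrame(
            repeat_rows, columns=["chrom", "start", "end", "label"])),
        chromatin_states=RegionSet(pd.DataFrame(
            ann_rows, columns=["chrom", "start", "end", "label"])),
        gene_features=RegionSet(pd.DataFrame(
            gene_rows, columns=["chrom", "start", "end", "label"])),
    )


def _plant_dmrs(
    params: SimulationParams, rng: np.random.Generator, cpg_pos: dict[str, np.ndarray]
) -> list[PlantedDMR]:
    """Place non-overlapping planted DMRs on coherent CpG runs.

    Only the first chromosome receives planted regions when several are
    declared, so the remaining chromosomes are guaranteed signal-free
    negative controls.
    """
    if params.n_planted_dmrs == 0:
        return []
    chrom = next(iter(cpg_pos))
    pos = cpg_pos[chrom]
    lo, hi = params.dmr_width_cpgs
    margin = 15  # keep clear of chromosome-block edges for flank analyses
    if pos.size < 2 * margin + hi:
        raise GenomeError(
            f"chromosome {chrom} has too few CpGs ({pos.size}) for planted DMRs"
        )
    taken: list[tuple[int, int]] = []  # claimed index ranges incl. separation
    planted: list[PlantedDMR] = []
    sep = params.min_dmr_separation_cpgs
    max_tries = 500 * params.n_planted_dmrs
    tries = 0
    while len(planted) < params.n_planted_dmrs:
        tries += 1
        if tries > max_tries:
            raise GenomeError(
                f"could not place {params.n_planted_dmrs} DMRs on {chrom}: "
                "chromosome too short or too fragmented"
            )
        w = int(rng.integers(lo, hi + 1))
        i = int(rng.integers(margin, pos.size - margin - w))
        j = i + w
        if any(i - sep < e and j + sep > s for s, e in taken):
            continue
        if np.diff(pos[i:j]).max(initial=0) > params.dmr_max_internal_gap:
            continue
        member = pos[i:j]
        k = len(planted) + 1
        center = 0.5 * (member[0] + member[-1])
        off = int(rng.integers(-params.snp_max_offset, params.snp_max_offset + 1))
        snp_pos = int(np.clip(round(center + off), 1, params.chrom_lengths[chrom]))
        planted.append(
            PlantedDMR(
                dmr_id=f"planted{k}",
                chrom=chrom,
                start=int(member[0]),
                end=int(member[-1]),
                member_pos=member.copy(),
                snp_id=f"planted{k}_snp",
                snp_pos=snp_pos,
                alt_is_methylated=bool(rng.integers(2)),
            )
        )
        taken.append((i, j))
    planted.sort(key=lambda d: d.start)
    for k, d in enumerate(planted, start=1):
        d.dmr_id = f"planted{k}"
        d.snp_id = f"planted{k}_snp"
    return planted


def _repeat_mask(
    params: SimulationParams, rng: np.random.Generator, planted: list[PlantedDMR]
) -> list[tuple]:
    """Random repeat intervals covering ~repeat_fraction, clear of planted DMRs."""
    rows: list[tuple] = []
    pad = 500
    for chrom, length in params.chrom_lengths.items():
        spans = [
            (d.start - 1 - pad, d.end + pad) for d in planted if d.chrom == chrom
        ]
        covered = 0
        target = params.repeat_fraction * length
        attempts = 0
        while covered < target and attempts < 100_000:
            attempts += 1
            size = 50 + int(rng.exponential(500))
            start = int(rng.integers(0, max(1, length - size)))
            end = start + size
            if any(start < e and end > s for s, e in spans):
                continue
            rows.append((chrom, start, end, "repeat"))
            covered += size
    return rows


def _truncated_poisson(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (resample zeros)."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def _flip(m: float, eps: float) -> float:
    return m * (1 - eps) + (1 - m) * eps


def methylated_allele_count(genotype: int, alt_is_methylated: bool) -> int:
    """Number of methylated-epiallele copies given an alt-allele dosage."""
    return genotype if alt_is_methylated else 2 - genotype


def simulate_site_reads(
    genotype: int,
    alt_is_methylated: bool,
    params: SimulationParams,
    n_reads: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Read-level simulation at one planted CpG for one sample.

    Returns (allele, methylated): the allele each read derives from
    (1 = alt) and its methylation call. Sorting reads by allele exposes
    the per-allele methylation split that validates allele-specific
    methylation at the read level.
    """
    alleles = rng.integers(0, 2, size=n_reads)  # which haplotype, 1 = alt
    carried = np.where(
        alleles == 1,
        1 if genotype >= 1 else 0,
        1 if genotype == 2 else 0,
    )
    # haplotype identity only matters for heterozygotes; homozygotes carry
    # the same allele on both haplotypes
    if genotype == 1:
        carried = alleles
    p_hi = _flip(params.m_hi, params.mosaicism)
    p_lo = _flip(params.m_lo, params.mosaicism)
    meth_allele = carried if alt_is_methylated else 1 - carried
    p = np.where(meth_allele == 1, p_hi, p_lo)
    methylated = rng.random(n_reads) < p
    return carried, methylated


def simulate_cohort(
    genome: Genome, params: SimulationParams, seed: int | None = None
) -> tuple[dict[str, pd.DataFrame], GenotypeTable, pd.DataFrame]:
    """Simulate per-sample methylomes, genotypes and the truth table.

    Returns ``(methylomes, genotypes, truth)`` where ``truth`` has one
    row per planted DMR with its causal SNP, orientation, per-sample
    genotypes and expected epigenotype classes.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    samples = params.samples
    n = len(samples)
    p_hi = _flip(params.m_hi, params.mosaicism)
    p_lo = _flip(params.m_lo, params.mosaicism)

    # genotypes at causal SNPs: HWE = Binomial(2, maf) alt-dosage draws
    causal_g = {d.dmr_id: rng.binomial(2, params.maf, size=n) for d in genome.planted}

    snp_rows = []
    for d in genome.planted:
        snp_rows.append([d.snp_id, d.chrom, d.snp_pos, *causal_g[d.dmr_id].astype(float)])
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], float)
    for b in range(params.n_background_snps):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        bp = int(rng.integers(1, genome.chrom_lengths[chroms[ci]] + 1))
        maf = rng.uniform(0.05, 0.5)
        snp_rows.append([f"bg{b + 1}", chroms[ci], bp, *rng.binomial(2, maf, size=n).astype(float)])
    genotypes = GenotypeTable(
        pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", *samples]), samples
    )

    # per-site methylation probability per sample
    planted_idx: dict[str, list[tuple[np.ndarray, str]]] = {}
    for d in genome.planted:
        idx = np.searchsorted(genome.cpg_pos[d.chrom], d.member_pos)
        planted_idx.setdefault(d.chrom, []).append((idx, d.dmr_id))

    methylomes: dict[str, pd.DataFrame] = {}
    per_sample_p: dict[str, np.ndarray] = {}
    for chrom in genome.cpg_pos:
        base = genome.bg_level[chrom]
        probs = np.tile(base, (n, 1))
        for idx, dmr_id in planted_idx.get(chrom, []):
            d = next(x for x in genome.planted if x.dmr_id == dmr_id)
            g = causal_g[dmr_id]
            a = np.array([methylated_allele_count(int(gi), d.alt_is_methylated) for gi in g])
            site_p = (a / 2.0) * p_hi + (1 - a / 2.0) * p_lo
            probs[:, idx] = site_p[:, None]
        per_sample_p[chrom] = probs

    for i, s in enumerate(samples):
        frames = []
        for chrom in genome.cpg_pos:
            pos = genome.cpg_pos[chrom]
            cov = _truncated_poisson(rng, params.coverage_lambda, pos.size)
            meth = rng.binomial(cov, per_sample_p[chrom][i])
            frames.append(
                make_methylome([chrom] * pos.size, pos, meth, cov)
            )
        methylomes[s] = pd.concat(frames, ignore_index=True)

    truth_rows = []
    for d in genome.planted:
        g = causal_g[d.dmr_id]
        row = {
            "dmr_id": d.dmr_id,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "n_cpgs": d.n_cpgs,
            "snp_id": d.snp_id,
            "snp_pos": d.snp_pos,
            "alt_is_methylated": d.alt_is_methylated,
        }
        for i, s in enumerate(samples):
            row[f"genotype_{s}"] = int(g[i])
            row[f"class_{s}"] = methylated_allele_count(int(g[i]), d.alt_is_methylated)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return methylomes, genotypes, truth


def simulate_null_cohort(
    params: SimulationParams, seed: int | None = None
) -> tuple[Genome, dict[str, pd.DataFrame], GenotypeTable, pd.DataFrame]:
    """A cohort with no planted differences (negative control)."""
    null_params = replace(params, n_planted_dmrs=0)
    genome = simulate_genome(null_params, seed=seed)
    methylomes, genotypes, truth = simulate_cohort(genome, null_params, seed=seed)
    return genome, methylomes, genotypes, truth


def write_truth(truth: pd.DataFrame, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    truth.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for _, r in truth.iterrows():
                fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['dmr_id']}\n")
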