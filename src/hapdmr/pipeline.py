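"""End-to-end orchestration: simulate -> align -> call -> null p values
-> epigenotype scoring -> flank profiles -> enrichment.

A run is configured by a :class:`RunConfig` (YAML-serializable); every
stochastic stage has an explicit seed, so identical configurations give
identical output bundles. Each stage writes to its own file in the
output directory and a manifest records parameters and per-stage record
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .caller import CallerParams, call_dmrs, dmrs_to_frame, write_dmrs_bed
from .io import align_cohort, read_genotypes, read_methylome, write_methylome
from .regions import enrichment_frame, enrichment_test, flank_profiles_frame
from .scoring import fit_beta_mixture, pooled_core_methylations, scan_window
from .significance import empirical_pvalues
from .simulate import SimulationParams, simulate_cohort, simulate_genome, write_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "hapdmr_run"
    seed: int = 0
    simulate: bool = True
    sim: SimulationParams = field(default_factory=SimulationParams)
    caller: CallerParams = field(default_factory=CallerParams)
    min_cov: int = 3
    null_replicates: int = 1000
    score_window_bp: int = 6000
    score_threshold: float = 0.9
    orientation_policy: str = "both"
    enrichment_sets: int = 10_000
    # file-mode inputs (used when simulate=False)
    methylome_paths: dict[str, str] = field(default_factory=dict)
    methylome_format: str = "bismark_cov"
    genotype_path: str | None = None
    genotype_format: str = "vcf_minimal"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d:
            sim = dict(d["sim"])
            if "dmr_width_cpgs" in sim:
                sim["dmr_width_cpgs"] = tuple(sim["dmr_width_cpgs"])
            d["sim"] = SimulationParams(**sim)
        if "caller" in d:
            d["caller"] = CallerParams(**d["caller"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Bundle of per-stage outputs of one run."""

    dmr_table: pd.DataFrame
    score_table: pd.DataFrame
    flank_table: pd.DataFrame
    enrichment_table: pd.DataFrame
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the result bundle to ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hapdmr_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    if config.simulate:
        genome = _stage("simulate")(simulate_genome)(config.sim, seed=config.seed)
        methylomes, genotypes, truth = _stage("simulate")(simulate_cohort)(
            genome, config.sim, seed=config.seed + 1
        )
        for s, m in methylomes.items():
            write_methylome(m, out / f"{s}.cov.tsv", "bismark_cov")
        write_truth(truth, out / "truth.tsv", out / "truth.bed")
        config.sim.to_yaml(out / "sim_params.yaml")
        cpg_positions = genome.cpg_pos
        chrom_lengths = genome.chrom_lengths
        annotation = genome.chromatin_states
        mask = genome.repeat_mask
        manifest["stages"]["simulate"] = {
            "n_cpgs": genome.n_cpgs,
            "n_planted": len(genome.planted),
            "n_snps": len(genotypes),
        }
    else:
        methylomes = {
            s: _stage("read")(read_methylome)(p, config.methylome_format)
            for s, p in config.methylome_paths.items()
        }
        genotypes = (
            _stage("read")(read_genotypes)(config.genotype_path, config.genotype_format)
            if config.genotype_path
            else None
        )
        cpg_positions = chrom_lengths = annotation = mask = None
        manifest["stages"]["read"] = {"n_methylomes": len(methylomes)}

    cohort = _stage("align")(align_cohort)(methylomes, min_cov=config.min_cov)
    manifest["stages"]["align"] = {
        "n_samples": cohort.n_samples, "n_sites": cohort.n_sites,
    }

    dmrs = _stage("call")(call_dmrs)(cohort, config.caller)
    manifest["stages"]["call"] = {"n_dmrs": len(dmrs)}

    if dmrs:
        dmrs, null = _stage("pvalue")(empirical_pvalues)(
            cohort, config.caller, R=config.null_replicates,
            seed=config.seed + 2, dmrs=dmrs,
        )
        manifest["stages"]["pvalue"] = {"R": null.R, "k": null.k}

    dmr_table = dmrs_to_frame(dmrs, cohort.samples)
    dmr_table.to_csv(out / "dmrs.tsv", sep="\t", index=False)
    if dmrs:
        write_dmrs_bed(dmrs, out / "dmrs.bed", cohort.samples)

    score_table = pd.DataFrame()
    if dmrs and genotypes is not None:
        values = pooled_core_methylations(dmrs)
        if values.size >= 9:
            mixture = _stage("score")(fit_beta_mixture)(values, seed=config.seed + 3)
            tables = [
                _stage("score")(scan_window)(
                    d, genotypes, mixture,
                    window_bp=config.score_window_bp,
                    threshold=config.score_threshold,
                    orientation_policy=config.orientation_policy,
                )
                for d in dmrs
            ]
            score_table = pd.concat(tables, ignore_index=True)
            manifest["stages"]["score"] = {
                "n_scored_pairs": int(sum(len(t) for t in tables)),
                "mixture_means": [float(x) for x in mixture.component_means()],
            }
        else:
            logger.warning("too few core methylation values (%d) to fit mixture", values.size)
    score_table.to_csv(out / "scores.tsv", sep="\t", index=False)

    flank_table = _stage("flanks")(flank_profiles_frame)(dmrs, cohort)
    flank_table.to_csv(out / "flanks.tsv", sep="\t", index=False)
    manifest["stages"]["flanks"] = {
        "n_lower_than_both": int((flank_table["classification"] == "lower_than_both").sum())
        if len(flank_table) else 0,
    }

    enrichment_table = pd.DataFrame()
    if dmrs and annotation is not None:
        intervals = pd.DataFrame(
            {"chrom": [d.chrom for d in dmrs],
             "start": [d.start - 1 for d in dmrs],
             "end": [d.end for d in dmrs]}
        )
        results = _stage("enrich")(enrichment_test)(
            intervals, annotation, cpg_positions, chrom_lengths,
            n_sets=config.enrichment_sets, seed=config.seed + 4, mask=mask,
        )
        enrichment_table = enrichment_frame(results)
        manifest["stages"]["enrich"] = {"n_labels": len(enrichment_table)}
    enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return PipelineResult(
        dmr_table=dmr_table,
        score_table=score_table,
        flank_table=flank_table,
        enrichment_table=enrichment_table,
        manifest=manifest,
    )
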