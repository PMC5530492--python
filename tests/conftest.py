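from __future__ import annotations

import numpy as np
import pytest

from hapdmr.io import CohortMatrix, compute_sigma, sort_chroms


def build_cohort(level, pos=None, chrom=None, cov=10, samples=None) -> CohortMatrix:
    """Construct an aligned cohort directly from a level matrix.

    ``level`` values must be exactly representable as meth/cov so that
    the stored counts reproduce them (keeps toy arithmetic exact).
    """
    level = np.asarray(level, float)
    n_samples, n_sites = level.shape
    cov = np.broadcast_to(np.asarray(cov, np.int64), level.shape).copy()
    meth = np.rint(level * cov).astype(np.int64)
    got = meth / cov
    assert np.allclose(got, level, atol=1e-12), "levels must be exact count ratios"
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    pos = np.asarray(pos, np.int64)
    if chrom is None:
        chrom = ["chr1"] * n_sites
    chrom = np.asarray(chrom, object)
    names = sort_chroms(chrom)
    code = {c: i for i, c in enumerate(names)}
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    return CohortMatrix(
        samples=list(samples),
        chrom=chrom,
        chrom_id=np.asarray([code[c] for c in chrom], np.int64),
        pos=pos,
        meth=meth,
        cov=cov,
        level=got,
        sigma=compute_sigma(got),
    )


def random_cohort(rng: np.random.Generator, max_sites: int = 200) -> CohortMatrix:
    """A random small cohort with extreme-prone levels, multi-chromosome
    layout and gap structure that exercises every caller branch."""
    n_samples = int(rng.integers(2, 6))
    n_sites = int(rng.integers(5, max_sites + 1))
    n_chrom = int(rng.integers(1, 3))
    split = sorted(rng.choice(np.arange(1, n_sites), size=n_chrom - 1, replace=False)) if n_chrom > 1 else []
    bounds = [0, *map(int, split), n_sites]
    chrom, pos = [], []
    for k in range(n_chrom):
        size = bounds[k + 1] - bounds[k]
        gaps = rng.integers(10, 400, size=size)
        pos.extend(np.cumsum(gaps) + 1)
        chrom.extend([f"chr{k + 1}"] * size)
    cov = rng.integers(3, 41, size=(n_samples, n_sites))
    raw = rng.beta(0.3, 0.3, size=(n_samples, n_sites))
    meth = np.rint(raw * cov).astype(np.int64)
    level = meth / cov
    names = sort_chroms(chrom)
    code = {c: i for i, c in enumerate(names)}
    return CohortMatrix(
        samples=[f"S{i + 1}" for i in range(n_samples)],
        chrom=np.asarray(chrom, object),
        chrom_id=np.asarray([code[c] for c in chrom], np.int64),
        pos=np.asarray(pos, np.int64),
        meth=meth,
        cov=cov,
        level=level,
        sigma=compute_sigma(level),
    )


@pytest.fixture(scope="session")
def small_study():
    """One small planted cohort shared by read-only tests."""
    from hapdmr.io import align_cohort
    from hapdmr.simulate import SimulationParams, simulate_cohort, simulate_genome

    params = SimulationParams(
        chrom_lengths={"chr1": 300_000}, n_planted_dmrs=8, seed=11
    )
    genome = simulate_genome(params, seed=11)
    methylomes, genotypes, truth = simulate_cohort(genome, params, seed=12)
    cohort = align_cohort(methylomes)
    return params, genome, methylomes, genotypes, truth, cohort
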