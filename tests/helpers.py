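"""Independent reference implementations used as test oracles.

These deliberately use plain python loops and elementary arithmetic so
they share no code path with the package implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_call(level, pos, chrom, v=0.5, min_cpgs=4, min_core_diff=0.8, max_gap=300):
    """Enumerate maximal qualifying runs directly from the level matrix.

    Returns half-open site-index ranges (a, b) of regions that satisfy
    every caller filter, computed with explicit loops.
    """
    n_samples = len(level)
    n_sites = len(level[0])
    sigma = []
    for c in range(n_sites):
        vals = [level[s][c] for s in range(n_samples)]
        m = sum(vals) / n_samples
        sigma.append(math.sqrt(sum((x - m) ** 2 for x in vals) / n_samples))
    t = [
        max(level[s][c] for s in range(n_samples))
        - min(level[s][c] for s in range(n_samples))
        for c in range(n_sites)
    ]

    results = []
    run: list[int] = []

    def close(members):
        if len(members) < min_cpgs:
            return
        ssum = sum(sigma[c] for c in members)
        if ssum == 0:
            diff = sum(t[c] for c in members) / len(members)
        else:
            diff = sum(sigma[c] * t[c] for c in members) / ssum
        if diff >= min_core_diff:
            results.append((members[0], members[-1] + 1))

    for c in range(n_sites):
        if t[c] > v:
            if run and (
                chrom[c] != chrom[run[-1]] or pos[c] - pos[run[-1]] > max_gap
            ):
                close(run)
                run = []
            run.append(c)
        else:
            if run:
                close(run)
            run = []
    if run:
        close(run)
    return results


def enumerate_detection_probability(p, n):
    """P(>=1 hom-methylated and >=1 hom-unmethylated among n HWE samples),
    by exhaustive enumeration of all 3^n genotype assignments."""
    q = 1.0 - p
    probs = {0: q * q, 1: 2 * p * q, 2: p * p}  # genotype = methylated-allele count
    total = 0.0
    for combo in itertools.product((0, 1, 2), repeat=n):
        if 0 in combo and 2 in combo:
            pr = 1.0
            for g in combo:
                pr *= probs[g]
            total += pr
    return total


def mc_detection_probability(p, n, draws, rng):
    """Monte-Carlo estimate with its standard error."""
    q = 1.0 - p
    g = rng.choice(3, size=(draws, n), p=[q * q, 2 * p * q, p * p])
    hit = ((g == 0).any(axis=1) & (g == 2).any(axis=1)).mean()
    se = math.sqrt(max(hit * (1 - hit), 1e-12) / draws)
    return hit, se
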