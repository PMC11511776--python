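"""Shared fixtures and independent brute-force oracles.

The oracles enumerate haplotype pairs explicitly and never reuse the
package's vectorised per-site formulas, so they can serve as an
independent check of pi, dxy and Hudson FST on small instances.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from ryescan.variant_io import MISSING, VariantMatrix


def make_matrix(dosages, chrom="chr1R", positions=None, depth=50.0, ref="A", alt="T"):
    """Build a VariantMatrix from a (sites x samples) dosage list."""
    G = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = G.shape
    pos = np.asarray(positions if positions is not None else np.arange(1, n_sites + 1))
    return VariantMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        ref=np.full(n_sites, ref, dtype=object),
        alt=np.full(n_sites, alt, dtype=object),
        genotypes=G,
        depth=np.full(n_sites, float(depth)) if np.isscalar(depth) else np.asarray(depth, float),
        samples=[f"s{i}" for i in range(n_samples)],
    )


def site_alleles(dosage_row):
    """Expand one site's dosages into a list of haploid alleles."""
    alleles = []
    for g in dosage_row:
        if g != MISSING:
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
    return alleles


def mean_pairwise_diff(alleles):
    """Average difference over all allele pairs; None if < 2 alleles."""
    if len(alleles) < 2:
        return None
    pairs = list(combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_pi(G, cols, window_length):
    """Mean pairwise differences per bp by explicit pair enumeration."""
    total = 0.0
    any_site = False
    for row in G[:, cols]:
        d = mean_pairwise_diff(site_alleles(row))
        if d is not None:
            total += d
            any_site = True
    return total / window_length if any_site else np.nan


def brute_dxy(G, cols1, cols2, window_length):
    """Mean between-population pairwise differences per bp."""
    total = 0.0
    any_site = False
    for row in G:
        a1, a2 = site_alleles(row[cols1]), site_alleles(row[cols2])
        if a1 and a2:
            pairs = list(product(a1, a2))
            total += sum(x != y for x, y in pairs) / len(pairs)
            any_site = True
    return total / window_length if any_site else np.nan


def brute_hudson_fst(G, cols1, cols2):
    """Ratio-of-sums 1 - sum(mean within het)/sum(between het) by pairs."""
    num = den = 0.0
    any_site = False
    for row in G:
        a1, a2 = site_alleles(row[cols1]), site_alleles(row[cols2])
        w1, w2 = mean_pairwise_diff(a1), mean_pairwise_diff(a2)
        if w1 is None or w2 is None:
            continue
        pairs = list(product(a1, a2))
        b = sum(x != y for x, y in pairs) / len(pairs)
        num += (w1 + w2) / 2
        den += b
        any_site = True
    if not any_site or den == 0:
        return np.nan
    return 1.0 - num / den


def brute_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + c, a + b  # term margin, study margin
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        probs[k] = comb(r1, k) * comb(n - r1, c1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def by_stepup(p_values):
    """Benjamini-Yekutieli adjusted p-values, direct step-up formula."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * c_m * p[i] / rank)
        adj[i] = min(1.0, running)
    return adj


@pytest.fixture
def small_config():
    from ryescan.simulate import SimulationConfig

    return SimulationConfig(
        n_chromosomes=6,
        chromosome_length=100_000_000,
        n_samples_pop1=50,
        n_samples_pop2=50,
        migration_1to2=0.0,
        migration_2to1=0.0,
        missing_rate=0.0,
        seed=11,
    )
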