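"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(literal double sums, all-pairs loops, fine-grid integration) so the tests
never share code paths with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from polysweep.haplotypes import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1)


def enumeration_expected_frequency(p: float, k: int, s: float, H: float) -> float:
    """Term-by-term genotype enumeration of the selection recursion.

    Written in the ancestral-count convention: genotype with i ancestral
    alleles (derived dosage d = k - i) transmits (k - i)/k derived alleles
    and has fitness 1 + h(k - i) * s with h(d) = (d/k)**(10**(-H)).
    """
    tau = 10.0 ** (-H)
    num = 0.0
    den = 0.0
    for i in range(k + 1):
        d = k - i
        h = (d / k) ** tau if d > 0 else 0.0
        geno = math.comb(k, i) * p ** (k - i) * (1 - p) ** i
        w = geno * (1 + h * s)
        num += w * (k - i) / k
        den += w
    return num / den


def brute_force_pi(sub: np.ndarray) -> float:
    """Sum over all haplotype pairs of per-pair differences (not per-bp)."""
    m = sub.shape[0]
    total = 0
    npairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            total += int(np.sum(sub[i] != sub[j]))
            npairs += 1
    return total / npairs


def brute_force_tajimas_d(sub: np.ndarray) -> float:
    """Textbook Tajima's D from the all-pairs pi sum and segregating sites."""
    m = sub.shape[0]
    c = sub.sum(axis=0)
    seg = (c > 0) & (c < m)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    pi = brute_force_pi(sub[:, seg])
    a1 = sum(1 / i for i in range(1, m))
    a2 = sum(1 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m**2 + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def random_matrix(rng, n_hap=10, n_sites=20, L=1000.0, two_pops=False) -> HaplotypeMatrix:
    """Random segregating 0/1 matrix with sorted distinct positions."""
    while True:
        data = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.uint8)
        c = data.sum(axis=0)
        keep = (c > 0) & (c < n_hap)
        if keep.sum() >= 2:
            data = data[:, keep]
            break
    S = data.shape[1]
    pos = np.sort(rng.choice(np.arange(1, int(L)), size=S, replace=False)).astype(float)
    if two_pops:
        sizes = (n_hap // 2, n_hap - n_hap // 2)
    else:
        sizes = (n_hap,)
    return HaplotypeMatrix(data, pos, sizes, k=2, L=L)
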