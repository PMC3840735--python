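"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the HWE oracle works
in exact rational arithmetic, the two-locus likelihood oracle maximises the
multinomial likelihood on a dense 1-D grid, and the haplotype-counting
oracle resolves phase directly when no double heterozygote is present.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_exact_enumeration(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_hom_a1 + n_het + n_hom_a2
    n_a1 = 2 * n_hom_a1 + n_het
    n_rare = min(n_a1, 2 * n - n_a1)
    if n_rare == 0:
        return 1.0
    probs = {}
    total = Fraction(0)
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # multinomial count of genotype configurations x 2^h phase choices
        w = Fraction(math.factorial(n), math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c)) * (2**h)
        probs[h] = w
        total += w
    p_obs = probs[n_het]
    tail = sum(w for w in probs.values() if w <= p_obs)
    return float(Fraction(tail, total))


def genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype table over jointly called samples."""
    valid = (g1 >= 0) & (g2 >= 0)
    counts = np.zeros((3, 3), dtype=int)
    for a in range(3):
        for b in range(3):
            counts[a, b] = int(((g1 == a) & (g2 == b) & valid).sum())
    return counts


def known_haplotype_counts(counts: np.ndarray) -> tuple[float, float, float, float, float]:
    """(k11, k12, k21, k22, n_double_het) haplotype tallies from a table."""
    c = counts.astype(float)
    k11 = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    k12 = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    k21 = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    k22 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    return k11, k12, k21, k22, float(c[1, 1])


def counting_haplotype_frequencies(counts: np.ndarray) -> np.ndarray:
    """Closed-form haplotype frequencies, valid only without double hets."""
    k11, k12, k21, k22, ndh = known_haplotype_counts(counts)
    assert ndh == 0, "counting solution requires no double heterozygotes"
    two_n = 2 * counts.sum()
    return np.array([k11, k12, k21, k22]) / two_n


def grid_max_f11(counts: np.ndarray, step: float = 1e-5) -> float:
    """Maximise the two-locus multinomial likelihood over f11 on a grid.

    The allele frequencies are the MLEs of the margins, leaving one free
    parameter; the likelihood is evaluated at every grid point in the
    feasible interval.
    """
    k11, k12, k21, k22, ndh = known_haplotype_counts(counts)
    two_n = 2 * counts.sum()
    p = (k11 + k12 + ndh) / two_n
    q = (k11 + k21 + ndh) / two_n
    lo = max(0.0, p + q - 1.0)
    hi = min(p, q)
    grid = np.arange(lo, hi + step / 2, step)
    f11 = grid
    f12 = p - f11
    f21 = q - f11
    f22 = 1 - p - q + f11

    def term(k, f):
        with np.errstate(divide="ignore"):
            t = k * np.log(np.where(f > 0, f, 1.0))
        return np.where(k > 0, np.where(f > 0, t, -np.inf), 0.0)

    dh = 2 * f11 * f22 + 2 * f12 * f21
    with np.errstate(divide="ignore"):
        dh_t = np.where(
            ndh > 0, np.where(dh > 0, ndh * np.log(np.where(dh > 0, dh, 1.0)), -np.inf), 0.0
        )
    ll = term(k11, f11) + term(k12, f12) + term(k21, f21) + term(k22, f22) + dh_t
    return float(grid[int(np.argmax(ll))])


def random_two_locus_sample(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unphased genotypes at two loci drawn from random haplotype
    frequencies (guaranteed polymorphic margins)."""
    while True:
        f = rng.dirichlet(np.ones(4))
        haps = rng.choice(4, size=(n, 2), p=f)
        # haplotype index: 0 = a1a1, 1 = a1a2, 2 = a2a1, 3 = a2a2
        g1 = (haps < 2).sum(axis=1)
        g2 = ((haps == 0) | (haps == 2)).sum(axis=1)
        if 0 < g1.sum() < 2 * n and 0 < g2.sum() < 2 * n:
            return g1.astype(np.int8), g2.astype(np.int8)
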