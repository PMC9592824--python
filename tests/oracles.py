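"""Independent exact-arithmetic oracles used to check the implementation.

Everything here is deliberately naive: brute-force pair enumeration and
Fraction arithmetic, sharing no code with the package paths it checks.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def brute_force_pi_total(haplotypes: np.ndarray) -> Fraction:
    """Exact mean pairwise Hamming distance over all haplotype pairs.

    ``haplotypes`` is sites x haplotypes with integer allele codes.
    """
    n = haplotypes.shape[1]
    total = Fraction(0)
    for i, j in combinations(range(n), 2):
        total += int(np.sum(haplotypes[:, i] != haplotypes[:, j]))
    return total / Fraction(n * (n - 1), 2)


def exact_tajimas_d(haplotypes: np.ndarray):
    """Tajima's D via exact fractions (float only for the final sqrt).

    Returns None when no site segregates.
    """
    n = haplotypes.shape[1]
    seg = [i for i in range(haplotypes.shape[0]) if len(set(haplotypes[i])) > 1]
    S = len(seg)
    if S == 0:
        return None
    pi_total = brute_force_pi_total(haplotypes[seg])
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(pi_total - Fraction(S) / a1) / float(var) ** 0.5


def exact_wc_theta(alt_counts, totals):
    """Haploid Weir-Cockerham theta for one site, in exact fractions.

    Transcribes the variance-component algebra step by step; returns
    (a, b, theta) as floats.
    """
    pops = [(Fraction(a), Fraction(t)) for a, t in zip(alt_counts, totals) if t > 0]
    r = len(pops)
    assert r >= 2
    n = [t for _, t in pops]
    p = [a / t for a, t in pops]
    n_bar = sum(n) / r
    n_C = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    inner = p_bar * (1 - p_bar) - s2 * Fraction(r - 1, r)
    a = (n_bar / n_C) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * inner
    theta = a / (a + b) if a + b != 0 else None
    return float(a), float(b), (float(theta) if theta is not None else None)


def random_haplotype_matrix(rng: np.random.Generator, max_hap=12, max_sites=20):
    """A random biallelic 0/1 matrix with at least one segregating site."""
    n = int(rng.integers(4, max_hap + 1))
    s = int(rng.integers(1, max_sites + 1))
    while True:
        m = (rng.random((s, n)) < rng.uniform(0.1, 0.9, size=(s, 1))).astype(np.int8)
        if np.any((m.sum(axis=1) > 0) & (m.sum(axis=1) < n)):
            return m
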