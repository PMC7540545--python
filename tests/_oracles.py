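"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by brute force (enumeration, grid
search, quadrature) along a code path disjoint from the implementation
it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.integrate import quad


def emission_by_enumeration(g1: int, g2: int, p: float) -> np.ndarray:
    """P(g1, g2 | IBD state) by enumerating parents and transmissions.

    Four parental alleles are Bernoulli(p); each sib independently picks
    one allele from each parent (16 equiprobable pick patterns).  The
    IBD state is the number of parents from whom both sibs picked the
    same allele copy.  Conditioning on the state and summing genotype
    matches gives the emission likelihood.
    """
    num = np.zeros(3)
    den = np.zeros(3)
    for alleles in product([0, 1], repeat=4):
        f, m = alleles[:2], alleles[2:]
        pa = math.prod(p if a == 1 else 1.0 - p for a in alleles)
        for i, j, k, l in product([0, 1], repeat=4):
            s = int(i == k) + int(j == l)
            w = pa / 16.0
            den[s] += w
            if f[i] + m[j] == g1 and f[k] + m[l] == g2:
                num[s] += w
    return num / den


def posteriors_by_path_enumeration(
    g1: np.ndarray, g2: np.ndarray, marker_map, error_rate: float = 0.0
) -> np.ndarray:
    """Exact IBD posteriors by summing over all 3^M hidden paths."""
    from sibshare.ibd import (
        IBD_PRIOR,
        emission_probs,
        haldane_theta,
        transition_matrix,
    )

    M = len(marker_map)
    freqs = marker_map["freq"].to_numpy(dtype=float)
    cm = marker_map["pos_cM"].to_numpy(dtype=float)
    emit = np.array(
        [
            emission_probs(int(g1[m]), int(g2[m]), float(freqs[m]), error_rate)
            for m in range(M)
        ]
    )
    trans = [
        transition_matrix(float(haldane_theta(cm[m + 1] - cm[m])))
        for m in range(M - 1)
    ]
    marginals = np.zeros((M, 3))
    total = 0.0
    for path in product(range(3), repeat=M):
        w = IBD_PRIOR[path[0]] * emit[0, path[0]]
        for m in range(1, M):
            w *= trans[m - 1][path[m - 1], path[m]] * emit[m, path[m]]
        total += w
        for m in range(M):
            marginals[m, path[m]] += w
    return marginals / total


def welch_p_by_quadrature(t: float, df: float) -> float:
    """Two-sided p-value from the t distribution via numerical quadrature."""

    def pdf(x: float) -> float:
        c = math.gamma((df + 1) / 2.0) / (
            math.sqrt(df * math.pi) * math.gamma(df / 2.0)
        )
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(pdf, abs(t), np.inf)
    return 2.0 * tail


def logistic_slope_by_grid(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-4
) -> float:
    """Logistic-regression slope by coarse-to-fine 2D grid search."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def nll(a: float, b: float) -> float:
        z = a + b * x
        return float(np.sum(np.logaddexp(0.0, z)) - np.sum(y * z))

    a_lo, a_hi, b_lo, b_hi = -5.0, 5.0, -5.0, 5.0
    step = 0.1
    best_a = best_b = 0.0
    while step >= tol / 2.0:
        a_grid = np.arange(a_lo, a_hi + step, step)
        b_grid = np.arange(b_lo, b_hi + step, step)
        vals = np.array([[nll(a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(np.argmin(vals), vals.shape)
        best_a, best_b = float(a_grid[ia]), float(b_grid[ib])
        a_lo, a_hi = best_a - 2 * step, best_a + 2 * step
        b_lo, b_hi = best_b - 2 * step, best_b + 2 * step
        step /= 10.0
    return best_b


def random_hmm_instance(rng: np.random.Generator, max_markers: int = 8):
    """A random single-chromosome genotype-pair instance for the HMM."""
    import pandas as pd

    M = int(rng.integers(2, max_markers + 1))
    cm = np.cumsum(rng.uniform(0.2, 25.0, size=M))
    marker_map = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos_bp": (cm * 1e6).astype(np.int64),
            "pos_cM": cm,
            "freq": rng.uniform(0.05, 0.95, size=M),
        }
    )
    g1 = rng.choice([-1, 0, 1, 2], size=M, p=[0.05, 0.3, 0.35, 0.3])
    g2 = rng.choice([-1, 0, 1, 2], size=M, p=[0.05, 0.3, 0.35, 0.3])
    return g1, g2, marker_map
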