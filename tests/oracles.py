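"""Independent brute-force oracles used to freeze expected values in tests.

Everything here is deliberately naive: explicit loops, exact rational
arithmetic, textbook definitions.  None of it shares code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, exp, pi, sqrt

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg step-up applied literally to a list of P-values."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    scaled = [p[order[r]] * n / (r + 1) for r in range(n)]
    # enforce monotone non-decreasing from the largest rank down, cap at 1
    for r in range(n - 2, -1, -1):
        scaled[r] = min(scaled[r], scaled[r + 1])
    scaled = [min(1.0, s) for s in scaled]
    out = [0.0] * n
    for r, i in enumerate(order):
        out[i] = scaled[r]
    return out


def chi2_df1_sf(x, n_steps=200_000):
    """Survival function of chi-square df=1 by trapezoid integration of the
    density f(t) = exp(-t/2) / sqrt(2 pi t), mapped through t = x + s^2 to
    remove the integrable singularity and compress the tail."""
    if x <= 0:
        return 1.0
    # substitute t = (sqrt(x) + s)^2, dt = 2 (sqrt(x)+s) ds, s in [0, inf)
    s = np.linspace(0.0, 40.0, n_steps)
    root = sqrt(x) + s
    t = root**2
    integrand = np.exp(-t / 2.0) / np.sqrt(2.0 * pi * t) * 2.0 * root
    return float(np.trapezoid(integrand, s))


def fisher_exact_enumerate(a, b, c, d):
    """Two-sided Fisher exact P by exact enumeration of same-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmfs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmfs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = pmfs[a]
    return float(sum(p for p in pmfs.values() if p <= p_obs))


def project_double_loop(x, y):
    """b_i = sum_j x_ij y_j with explicit loops."""
    n, m = x.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            out[i] += x[i, j] * y[j]
    return out


def collapse_triple_loop(mrna, mirna):
    """x_ik = sum_j x_ij x_kj with explicit loops."""
    n, m = mrna.shape
    k = mirna.shape[0]
    out = np.zeros((n, k))
    for i in range(n):
        for kk in range(k):
            for j in range(m):
                out[i, kk] += mrna[i, j] * mirna[kk, j]
    return out


def population_sd(values):
    values = list(values)
    mean = sum(values) / len(values)
    return sqrt(sum((v - mean) ** 2 for v in values) / len(values))
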