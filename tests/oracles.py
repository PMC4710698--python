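"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: the BH oracle is a direct
double-loop step-up, the hypergeometric oracle sums exact math.comb
probabilities, and the Pearson oracle is the textbook sum formula.
"""

import math

import numpy as np


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up definition.

    For the i-th smallest p-value the adjusted value is
    min over j >= i of (m * p_(j) / j), capped at 1.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order):  # rank_pos 0-based
        best = 1.0
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            cand = m * p[order[later_pos]] / j
            if cand < best:
                best = cand
        adj[i] = best
    return adj


def hypergeom_pmf_exact(k, N, K, n):
    """Exact hypergeometric pmf via math.comb (float of an exact rational)."""
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_two_sided(k, N, K, n, tol=1e-9):
    """Two-sided p: sum of pmf over all k' with pmf(k') <= pmf(k)(1+tol)."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    pk = hypergeom_pmf_exact(k, N, K, n)
    total = 0.0
    for kk in range(lo, hi + 1):
        q = hypergeom_pmf_exact(kk, N, K, n)
        if q <= pk * (1 + tol):
            total += q
    return min(total, 1.0)


def pearson_textbook(x, y):
    """Pearson r by the raw sum formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx * sx) * math.sqrt(n * (y * y).sum() - sy * sy)
    return num / den


def quantile_linear(values, q):
    """q-th quantile with linear interpolation between order statistics."""
    v = sorted(values)
    n = len(v)
    pos = q * (n - 1)
    i = int(math.floor(pos))
    frac = pos - i
    if i + 1 < n:
        return v[i] + frac * (v[i + 1] - v[i])
    return v[i]
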