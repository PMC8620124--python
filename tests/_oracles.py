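"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct formula evaluation and
exhaustive enumeration — and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def chisquare_equal(counts) -> float:
    """Sum (O-E)^2 / E against equal expected proportions."""
    counts = list(counts)
    e = sum(counts) / len(counts)
    return sum((o - e) ** 2 / e for o in counts)


def chisquare_independence(table) -> float:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    margin-preserving tables no more probable than the observed one."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def poisson_newton_raphson(X, y, tol=1e-12, iters=200) -> np.ndarray:
    """Log-link Poisson ML estimates by plain Newton-Raphson."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean())
    for _ in range(iters):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def spearman_rho(x, y) -> float:
    """1 - 6 sum d^2 / (n (n^2 - 1)); valid for untied data."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = x.argsort().argsort() + 1
    ry = y.argsort().argsort() + 1
    n = len(x)
    return 1.0 - 6.0 * float(np.sum((rx - ry) ** 2)) / (n * (n ** 2 - 1))


def best_bipartition_gini(levels, y_by_level):
    """Exhaustive best Gini-gain bipartition of categorical levels.

    ``y_by_level`` maps level -> array of 0/1 outcomes.  Returns
    (best gain, frozenset of best left set).
    """
    def gini_sum(ys):
        n = len(ys)
        if n == 0:
            return 0.0
        p = np.mean(ys)
        return n * 2 * p * (1 - p)

    levels = sorted(levels)
    all_y = np.concatenate([y_by_level[lv] for lv in levels])
    parent = gini_sum(all_y)
    best_gain, best_left = -1.0, None
    for k in range(1, len(levels)):
        for left in combinations(levels, k):
            yl = np.concatenate([y_by_level[lv] for lv in left])
            yr = np.concatenate([y_by_level[lv] for lv in levels
                                 if lv not in left])
            gain = parent - gini_sum(yl) - gini_sum(yr)
            if gain > best_gain + 1e-12:
                best_gain, best_left = gain, frozenset(left)
    return best_gain, best_left


def best_bipartition_sse(levels, y_by_level):
    """Exhaustive best SSE-reduction bipartition for regression."""
    def sse(ys):
        return float(np.sum((ys - ys.mean()) ** 2)) if len(ys) else 0.0

    levels = sorted(levels)
    all_y = np.concatenate([y_by_level[lv] for lv in levels])
    parent = sse(all_y)
    best_gain, best_left = -1.0, None
    for k in range(1, len(levels)):
        for left in combinations(levels, k):
            yl = np.concatenate([y_by_level[lv] for lv in left])
            yr = np.concatenate([y_by_level[lv] for lv in levels
                                 if lv not in left])
            gain = parent - sse(yl) - sse(yr)
            if gain > best_gain + 1e-12:
                best_gain, best_left = gain, frozenset(left)
    return best_gain, best_left
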