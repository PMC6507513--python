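"""Independent brute-force oracles used to cross-check the statistics."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def mann_whitney_exact_bruteforce(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    U is the count of (a_i, b_j) pairs with a_i > b_j. The two-sided p is
    2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1 — the standard
    exact-distribution convention for tie-free data.
    """
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(x > y for x in ga for y in gb))
    us = np.array(us)
    n_total = len(us)
    p_le = np.sum(us <= u_obs) / n_total
    p_ge = np.sum(us >= u_obs) / n_total
    return float(u_obs), float(min(1.0, 2 * min(p_le, p_ge)))


def bh_stepup_direct(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted values straight from the step-up rule:
    q(i) = min over j >= i of (m * p(j) / j), on the sorted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def binomial_upper_tail_direct(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of the binomial pmf."""
    return float(sum(comb(n, j) * p**j * (1 - p) ** (n - j)
                     for j in range(k, n + 1)))
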