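"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: exact test p-values are
recomputed by direct enumeration so the implementations can be checked
against first principles.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first sample (tie-free data only).

    Returns (U = min(U_x, U_y), p = 2 * min tail, capped at 1).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    r1 = sum(ranks[v] for v in x)
    u_x = r1 - n1 * (n1 + 1) / 2
    total = comb(n1 + n2, n1)
    n_le = n_ge = 0
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        if u <= u_x:
            n_le += 1
        if u >= u_x:
            n_ge += 1
    p = 2 * min(n_le, n_ge) / total
    return min(u_x, n1 * n2 - u_x), min(p, 1.0)


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating every table with the observed
    margins and summing the probabilities not exceeding the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa: int) -> float:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )


def bh_stepup(pvals) -> np.ndarray:
    """Hand application of the BH step-up formula with cumulative minimum."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def venn_brute_force(sets: dict[str, set]) -> dict[str, int]:
    """Region counts by testing every element's membership pattern."""
    names = list(sets)
    counts: dict[str, int] = {}
    for elem in set().union(*sets.values()):
        key = "&".join(n for n in names if elem in sets[n])
        counts[key] = counts.get(key, 0) + 1
    return counts


def km_by_hand(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate computed with explicit risk-set bookkeeping."""
    pairs = sorted(zip(times, events))
    s = 1.0
    out = []
    i = 0
    n = len(pairs)
    while i < n:
        t = pairs[i][0]
        d = sum(1 for tt, ee in pairs if tt == t and ee == 1)
        at_risk = sum(1 for tt, _ in pairs if tt >= t)
        if d > 0:
            s *= 1 - d / at_risk
            out.append((t, s))
        i += sum(1 for tt, _ in pairs if tt == t)
    return out
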