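"""Independent brute-force oracles used by the unit and acceptance suites.

These are deliberately written from the textbook definitions (pmf
summation, rank-then-Pearson, Pearson's chi-square formula, pooled- and
unpooled-variance t statistics) and never call the library code paths they
are used to check.
"""
import math

import numpy as np


def poisson_upper_tail(k: int, lam: float, terms: int = 4000) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct pmf summation in log space."""
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = 0.0
    for j in range(k, k + terms):
        total += math.exp(j * math.log(lam) - lam - math.lgamma(j + 1))
    return min(total, 1.0)


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def bh_bruteforce(pvals):
    """q_i = min over p_(j) >= p_(i) of p_(j) * n / j, from the definition."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def midrank(v):
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    sv = np.asarray(v)[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> float:
    """Mid-rank ties, then the Pearson correlation of the ranks."""
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def chi2_bruteforce(table) -> float:
    """Pearson's statistic: sum (O - E)^2 / E with E from the margins."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def student_t_bruteforce(a, b) -> float:
    """Pooled-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def welch_t_bruteforce(a, b):
    """Welch's unpooled t statistic and Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(t), float(df)
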