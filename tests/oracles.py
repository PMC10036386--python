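"""Independent brute-force oracles for the exact tests.

Pure-Python enumeration, sharing no code with the implementations they
check: midranks are computed by hand, tail counting walks explicit
subsets, and the hypergeometric pmf is built from math.comb.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p: double the smaller tail over all labelings."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    nx, n = len(x), len(pooled)
    observed = sum(ranks[:nx])
    eps = 1e-9
    n_le = n_ge = total = 0
    for subset in combinations(range(n), nx):
        s = sum(ranks[i] for i in subset)
        total += 1
        if s <= observed + eps:
            n_le += 1
        if s >= observed - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def fisher_exact_oracle(a, b, c, d) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
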