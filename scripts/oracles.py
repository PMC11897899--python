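"""Independent enumeration oracles used by the acceptance script.

Deliberately avoid the package's own code paths: the Fisher oracle works
from log-factorials, the Mann-Whitney oracle enumerates subsets of
hand-computed mid-ranks.
"""

from __future__ import annotations

import itertools
import math


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by cumulative sum over the hypergeometric support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lf = [0.0] * (n + 1)
    for i in range(2, n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    def logp(k: int) -> float:
        a_, b_, c_, d_ = k, row1 - k, col1 - k, n - row1 - col1 + k
        return (
            lf[row1] + lf[n - row1] + lf[col1] + lf[n - col1]
            - lf[n] - lf[a_] - lf[b_] - lf[c_] - lf[d_]
        )

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    p_obs = logp(a)
    total = sum(
        math.exp(lp)
        for k in range(k_min, k_max + 1)
        if (lp := logp(k)) <= p_obs + 1e-7
    )
    return min(1.0, total)


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mwu_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p over all C(m+n, m) mid-rank subsets."""
    pooled = list(x) + list(y)
    m = len(x)
    ranks = _midranks(pooled)
    offset = m * (m + 1) / 2.0
    u_obs = sum(ranks[:m]) - offset
    lower = upper = total = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        u = sum(ranks[i] for i in combo) - offset
        total += 1
        lower += u <= u_obs + 1e-9
        upper += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(lower, upper) / total)
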