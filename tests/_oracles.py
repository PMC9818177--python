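"""Independent reference implementations used only by the tests.

Each oracle is written from the textbook definition, scalar and loop-based,
deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

from scipy import stats


def pooled_t_p_value(a, b) -> float:
    """Two-sample pooled-variance Student t-test, from the textbook formula."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((x - m1) ** 2 for x in a)
    ss2 = sum((x - m2) ** 2 for x in b)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    if sp2 == 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(abs(t), df)


def hypergeom_upper_p_bruteforce(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for i in range(m, min(n, M) + 1):
        acc += math.comb(M, i) * math.comb(N - M, n - i)
    return acc / total


def hypergeom_lower_cdf_bruteforce(N: int, n: int, M: int, m: int) -> float:
    """P(X <= m) by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for i in range(0, min(m, min(n, M)) + 1):
        acc += math.comb(M, i) * math.comb(N - M, n - i)
    return acc / total


def auc_by_pair_concordance(values, is_case) -> float:
    """AUC as the fraction of concordant case/control pairs (ties count 0.5)."""
    cases = [v for v, c in zip(values, is_case) if c]
    controls = [v for v, c in zip(values, is_case) if not c]
    acc = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                acc += 1.0
            elif x == y:
                acc += 0.5
    return acc / (len(cases) * len(controls))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p via scipy's scalar routine."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
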