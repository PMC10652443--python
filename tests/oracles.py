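"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: binomial tails are
summed term by term from log-space pmf values, and the two-sided Fisher
p-value is obtained by full hypergeometric enumeration.
"""

import math

import numpy as np
from scipy.special import gammaln


def binom_tail_bruteforce(k: int, n: int, p: float) -> float:
    """P(X >= k), X ~ Binomial(n, p), by direct log-space pmf summation."""
    if k <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.exp(
            math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1)
            + j * math.log(p) + (n - j) * math.log1p(-p)
        )
    return min(total, 1.0)


def binom_all_tails(n: int, p: float) -> np.ndarray:
    """Vector of P(X >= k) for k = 0..n via reversed cumulative pmf sums."""
    k = np.arange(n + 1)
    if p == 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p == 1.0:
        return np.ones(n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )
    return np.cumsum(np.exp(logpmf)[::-1])[::-1]


def hypergeom_logpmf(x: int, r1: int, c1: int, n: int) -> float:
    return (
        math.lgamma(c1 + 1) - math.lgamma(x + 1) - math.lgamma(c1 - x + 1)
        + math.lgamma(n - c1 + 1) - math.lgamma(r1 - x + 1)
        - math.lgamma(n - c1 - r1 + x + 1)
        - (math.lgamma(n + 1) - math.lgamma(r1 + 1) - math.lgamma(n - r1 + 1))
    )


def fisher_twosided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all hypergeometric outcomes no more
    probable than the observed table (with a relative tolerance for ties)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: math.exp(hypergeom_logpmf(x, r1, c1, n)) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-12)))


def chi2_2x2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square statistic sum((O-E)^2/E) on a 2x2 table."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def bh_stepup_bruteforce(pvalues):
    """Benjamini-Hochberg by the textbook step-up recipe."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted
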