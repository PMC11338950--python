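"""Independent oracles for the statistical primitives.

These deliberately avoid the code paths (and where possible the library
routines) used by the implementation: the t-tail is obtained by numeric
integration of the explicit t density, and the hypergeometric tails by exact
big-integer binomial sums.
"""

import math
from fractions import Fraction

from scipy.integrate import quad


def t_density(x: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1.0 + x * x / df) ** (-(df + 1) / 2)


def ttest_p_oracle(t: float, df: int) -> float:
    """Two-sided p by numeric integration of the t density."""
    tail, _ = quad(t_density, abs(t), math.inf, args=(df,))
    return 2.0 * tail


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact big-integer arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(max(k, 0, n - (N - K)), min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(min(acc, Fraction(1)))


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for [[a, b], [c, d]]."""
    return hypergeom_tail_oracle(a, a + b + c + d, a + c, a + b)


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg computed directly from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q
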