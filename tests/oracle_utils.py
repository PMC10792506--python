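"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive and exact (rational arithmetic,
exhaustive enumeration) and shares no code with the package implementation.
"""

from fractions import Fraction
from math import comb, sqrt

from scipy import stats


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact enumeration."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def binom_upper_tail_patterns(k: int, n: int, p0: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p0) by summing over all 2^n outcome
    patterns (each pattern weighted by p0^ones * (1-p0)^zeros)."""
    q0 = 1 - p0
    acc = Fraction(0)
    for pattern in range(2**n):
        ones = bin(pattern).count("1")
        if ones >= k:
            acc += p0**ones * q0 ** (n - ones)
    return acc


def welch_two_sided(a: list[float], b: list[float]) -> tuple[float, float]:
    """Textbook Welch unequal-variance two-group test: returns
    (mean(a) - mean(b), two-sided p)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return ma - mb, 2 * stats.t.sf(abs(t), df)
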