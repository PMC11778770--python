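"""Independent re-derivations used as test oracles.

These deliberately avoid the code paths they check: exact integer
enumeration for Fisher's test, the pooled two-proportion z-statistic for the
chi-squared identity, and a direct search over the exact finite-population
Wald half-width for sample sizes.
"""

import math


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose probability
    does not exceed the observed table's (minimum-likelihood definition).
    Exact integer arithmetic, so ties are decided exactly.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = math.comb(n, c1)
    return sum(w for w in weights.values() if w <= w_obs) / total


def two_proportion_z_squared(x1: int, n1: int, x2: int, n2: int) -> float:
    """Square of the pooled two-proportion z-statistic (no correction)."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return 0.0
    return (p1 - p2) ** 2 / var


def wald_ci_direct(count: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Textbook normal-approximation CI in percent, clipped to [0, 100]."""
    p = count / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half))


def smallest_n_exact_fpc(N: int, p: float, e: float, z: float = 1.96) -> int:
    """Smallest n whose exact finite-population Wald half-width is <= e.

    Half-width: z * sqrt((p(1-p)/n) * (N-n)/(N-1)). Brute-force search.
    """
    if N == 1:
        return 1
    for n in range(1, N + 1):
        half = z * math.sqrt((p * (1.0 - p) / n) * (N - n) / (N - 1))
        if half <= e:
            return n
    return N
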