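"""Independent oracles used to pin expected values in tests.

These deliberately avoid the code paths they check: exact rational
arithmetic for the Hardy-Weinberg conditional distribution, and direct
normal-equation solves for residualization.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by exhaustive enumeration with rational arithmetic.

    Conditions on the allele counts; enumerates every heterozygote count of
    the right parity, computes each table's conditional probability as an
    exact Fraction, and sums those with probability <= the observed table's.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    n_b = 2 * n_aa + n_Aa
    rare, common = min(n_a, n_b), max(n_a, n_b)
    if rare == 0:
        return 1.0

    def weight(het: int) -> Fraction:
        # unnormalized: 2^het / (n_rare_hom! het! n_common_hom!)
        n_rr = (rare - het) // 2
        n_cc = (common - het) // 2
        return Fraction(2 ** het,
                        factorial(n_rr) * factorial(het) * factorial(n_cc))

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


def residuals_by_normal_equations(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals via the hat matrix from explicitly solved normal
    equations (intercept prepended)."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    return y - D @ beta


def pearson_by_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation from the raw covariance/SD definition."""
    n = len(x)
    cov = (x * y).sum() / n - x.mean() * y.mean()
    sx = np.sqrt((x ** 2).sum() / n - x.mean() ** 2)
    sy = np.sqrt((y ** 2).sum() / n - y.mean() ** 2)
    return cov / (sx * sy)
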