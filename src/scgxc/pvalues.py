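"""Tail probabilities of positively weighted sums of 1-df chi-square variables.

The score-test null distribution is ``sum_i lambda_i * chi2_1``.  The exact
survival function is evaluated with Ruben's series expansion: a mixture of
central chi-square tails with nonnegative coefficients summing to one, so the
truncation error is rigorously bounded by the unassigned coefficient mass and
small p-values come out without cancellation.  A three-moment non-central
chi-square approximation (Liu-Tang-Zhang, as used by SKAT) serves as fallback
when the series converges too slowly (extreme weight spread).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mixture_chi2_sf", "exact_sf", "liu_sf", "P_FLOOR"]

P_FLOOR = 1e-30


def exact_sf(
    q: float,
    weights: np.ndarray,
    eps: float = 1e-12,
    max_terms: int = 20_000,
) -> tuple[float, float]:
    """``P(sum_i w_i chi2_1 > q)`` by Ruben's chi-square series.

    With ``beta = min(w)`` the mixture tail expands as
    ``sum_k a_k * SF_chi2(q / beta; K + 2k)`` with ``a_k >= 0`` and
    ``sum_k a_k = 1``; the series is truncated once the remaining coefficient
    mass drops below ``eps``.  Returns ``(p, error_bound)``; the error bound
    exceeds ``eps`` if the term budget was exhausted before convergence.
    """
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    K = w.size
    beta = w.min()
    x = q / beta
    t = 1.0 - beta / w                     # all in [0, 1)
    a0 = float(np.exp(0.5 * np.sum(np.log(beta / w))))
    a = np.empty(max_terms)
    b = np.empty(max_terms + 1)
    a[0] = a0
    sf = a0 * float(stats.chi2.sf(x, K))
    mass = a0
    t_pow = np.ones(K)
    k = 0
    chunk = 64
    while mass < 1.0 - eps and k + 1 < max_terms:
        hi = min(k + chunk, max_terms - 1)
        dfs = K + 2 * np.arange(k + 1, hi + 1)
        sf_terms = stats.chi2.sf(x, dfs)
        for j, kk in enumerate(range(k + 1, hi + 1)):
            t_pow *= t
            b[kk] = float(np.sum(t_pow))
            a[kk] = 0.5 / kk * float(b[1 : kk + 1] @ a[kk - 1 :: -1])
            sf += a[kk] * float(sf_terms[j])
            mass += a[kk]
            if mass >= 1.0 - eps:
                break
        k = hi
    return min(sf, 1.0), max(1.0 - mass, 0.0)


def liu_sf(q: float, weights: np.ndarray) -> float:
    """Three-moment non-central chi-square approximation of the mixture tail."""
    w = np.asarray(weights, dtype=float)
    c1, c2, c3, c4 = (np.sum(w**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2.0 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
        a = np.sqrt(dof)
    mu_x = dof + delta
    sigma_x = np.sqrt(2.0) * a
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, dof, delta))
    return float(stats.chi2.sf(x, dof))


def mixture_chi2_sf(q: float, weights: np.ndarray) -> tuple[float, str]:
    """Survival probability of the weighted chi-square mixture at ``q``.

    Uses the exact series first and the Liu approximation only when the
    series fails to converge within its term budget.  Returns
    ``(p, method_flag)`` with ``method_flag`` in {"davies", "liu_fallback",
    "degenerate"} and p floored at 1e-30.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "davies"
    p, err = exact_sf(q, w)
    if err < max(1e-10, 0.01 * p):
        return max(min(p, 1.0), P_FLOOR), "davies"
    return max(min(liu_sf(q, w), 1.0), P_FLOOR), "liu_fallback"
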