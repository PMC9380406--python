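"""Hypothesis tests: the GxC variance-component score test, the persistent-effect
likelihood-ratio test, and fixed-effect comparator tests.

The score test follows the SKAT construction: with null covariance ``K0`` and
GxC kernel factor ``F = diag(g) C``, the statistic is
``Q = 1/2 * r' K0^-1 F F' K0^-1 r`` and its null distribution is the weighted
chi-square mixture with weights given by the eigenvalues of
``1/2 * F' P0 F`` -- a k x k problem, never an N x N one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from scgxc.covariance import LowRankCovariance
from scgxc.null_model import FixedDesign, GramKernel, NullFit, fit_variance_components
from scgxc.preprocessing import DegenerateInputError, ExpressionVector, GenotypeVector
from scgxc.pvalues import mixture_chi2_sf

__all__ = [
    "GxcResult",
    "AssocResult",
    "interaction_score_test",
    "association_lrt",
    "single_env_lrt",
    "multi_env_lrt",
    "interaction_test_no_relatedness",
]

_WEIGHT_TOL = 1e-12


@dataclass
class GxcResult:
    """Outcome of a GxC score test for one gene-variant pair."""

    gene_id: str
    variant_id: str
    statistic: float
    pvalue: float
    eigen_weights: np.ndarray
    method_flags: str
    fit: NullFit | None = field(default=None, repr=False)


@dataclass
class AssocResult:
    """Outcome of the persistent-effect (association) LRT."""

    gene_id: str
    variant_id: str
    beta_G: float
    lrt_stat: float
    pvalue: float
    mode: str = "exact"
    fit: NullFit | None = field(default=None, repr=False)


def _as_values(y) -> np.ndarray:
    if isinstance(y, ExpressionVector):
        return y.values
    return np.asarray(y, dtype=float)


def _as_cells(g) -> np.ndarray:
    if isinstance(g, GenotypeVector):
        if g.expanded is None:
            raise ValueError("genotype must be expanded to cells")
        return g.expanded
    return np.asarray(g, dtype=float)


def _check_nonconstant(g_cells: np.ndarray, what: str = "genotype") -> None:
    if np.allclose(g_cells, g_cells[0]):
        raise DegenerateInputError(f"{what} is constant across cells: unestimable")


def _score_test(fit: NullFit, F: np.ndarray, gene_id: str, variant_id: str) -> GxcResult:
    """Score statistic, mixture weights and p-value given a fitted null."""
    KiR = fit.solve(fit.residual)
    half_score = F.T @ KiR
    Q = 0.5 * float(half_score @ half_score)
    PF = fit.project(F)
    S = 0.5 * (F.T @ PF)
    S = 0.5 * (S + S.T)
    lam = np.linalg.eigvalsh(S)
    if lam.size and lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise RuntimeError("score-test weight matrix is not PSD; null fit may be invalid")
    lam = lam[lam > _WEIGHT_TOL * max(lam.max(), _WEIGHT_TOL)]
    p, flag = mixture_chi2_sf(Q, lam)
    return GxcResult(
        gene_id=gene_id,
        variant_id=variant_id,
        statistic=Q,
        pvalue=p,
        eigen_weights=lam,
        method_flags=flag,
        fit=fit,
    )


def interaction_score_test(
    y,
    g,
    X: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    fit: NullFit | None = None,
    gene_id: str = "gene",
    variant_id: str = "variant",
    n_starts: int = 3,
) -> GxcResult:
    """Variance-component score test for GxC interaction effects.

    The null model ``y = X b + u + c + e`` (genotype as a fixed-effect column
    of ``X``) is fitted by REML unless a ``fit`` is supplied, then the score
    statistic for the ``diag(g) Sigma diag(g)`` component is evaluated at the
    null optimum.
    """
    y = _as_values(y)
    g_cells = _as_cells(g)
    _check_nonconstant(g_cells)
    if fit is None:
        fit = fit_variance_components(
            y, X, [RSigma, Sigma], method="reml", n_starts=n_starts
        )
    F = g_cells[:, None] * Sigma.factor
    return _score_test(fit, F, gene_id, variant_id)


def association_lrt(
    y,
    g,
    X_nogeno: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    mode: str = "exact",
    null_fit: NullFit | None = None,
    gene_id: str = "gene",
    variant_id: str = "variant",
    n_starts: int = 3,
) -> AssocResult:
    """Likelihood-ratio test of the persistent genetic effect ``beta_G != 0``.

    ``mode="exact"`` refits the variance components under the alternative;
    ``mode="fast"`` keeps the variance components from the genotype-free null
    and only refits the fixed effects by GLS (a Wald-type approximation used
    for discovery scans; flagged in the result).
    """
    y = _as_values(y)
    g_cells = _as_cells(g)
    _check_nonconstant(g_cells)
    design0 = X_nogeno if isinstance(X_nogeno, FixedDesign) else FixedDesign(X_nogeno)
    design1 = design0.with_column(g_cells, "genotype")
    terms = [RSigma, Sigma]
    if null_fit is None:
        null_fit = fit_variance_components(
            y, design0, terms, method="ml", n_starts=n_starts
        )
    if mode == "exact":
        alt = fit_variance_components(y, design1, terms, method="ml", n_starts=n_starts)
        ll1, beta = alt.loglik, alt.beta
    elif mode == "fast":
        scales = [null_fit.variances[t.description or f"term_{i}"] for i, t in enumerate(terms)]
        kernel1 = GramKernel(y, design1.X, [t.factor for t in terms])
        noise = null_fit.variances["noise"]
        ll1 = kernel1.loglik(scales, noise, reml=False)
        beta = kernel1.gls_beta(scales, noise)
    else:
        raise ValueError("mode must be 'exact' or 'fast'")
    lrt = 2.0 * (ll1 - null_fit.loglik)
    if lrt < -1e-6:
        raise RuntimeError(f"alternative log-likelihood below null by {-lrt / 2:.2e}")
    lrt = max(lrt, 0.0)
    return AssocResult(
        gene_id=gene_id,
        variant_id=variant_id,
        beta_G=float(beta[-1]),
        lrt_stat=float(lrt),
        pvalue=float(stats.chi2.sf(lrt, df=1)),
        mode=mode,
        fit=null_fit,
    )


def single_env_lrt(
    y,
    g,
    X: FixedDesign | np.ndarray,
    contexts,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    fit: NullFit | None = None,
    n_starts: int = 3,
) -> float:
    """Fixed-effect interaction LRT per context, Bonferroni-combined.

    For each context ``c_j`` the column ``g * c_j`` is added to the design
    and tested with a 1-df LRT at the null variance components; the minimum
    p-value times the number of contexts (capped at 1) is returned.  Shares
    the random-effect background with the score test.

    With the covariance fixed, adding one GLS regressor ``f`` improves
    ``2 * loglik`` by exactly ``(f' P0 y)^2 / (f' P0 f)``, so all k
    statistics come from a single projector application.
    """
    y = _as_values(y)
    g_cells = _as_cells(g)
    _check_nonconstant(g_cells)
    C = contexts.values if hasattr(contexts, "values") else np.asarray(contexts, float)
    design0 = X if isinstance(X, FixedDesign) else FixedDesign(X)
    if fit is None:
        fit = fit_variance_components(
            y, design0, [RSigma, Sigma], method="reml", n_starts=n_starts
        )
    k = C.shape[1]
    F = g_cells[:, None] * C
    PF = fit.project(F)
    num = (PF.T @ y) ** 2
    den = np.einsum("ij,ij->j", F, PF)
    stat = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    pvals = stats.chi2.sf(stat, df=1)
    return float(min(pvals.min() * k, 1.0))


def multi_env_lrt(
    y,
    g,
    X: FixedDesign | np.ndarray,
    contexts,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    fit: NullFit | None = None,
    n_starts: int = 3,
) -> float:
    """Joint k-df fixed-effect interaction LRT (benchmarking comparator only).

    This is a genuine likelihood-ratio test: variance components are refit by
    ML under both the null and the alternative (all ``k`` interaction columns
    added at once).  Known not to retain calibration as the number of
    contexts grows; provided to reproduce that behavior in benchmarks, not
    for production use.  A supplied ``fit`` only seeds the optimizer.
    """
    y = _as_values(y)
    g_cells = _as_cells(g)
    _check_nonconstant(g_cells)
    C = contexts.values if hasattr(contexts, "values") else np.asarray(contexts, float)
    design0 = X if isinstance(X, FixedDesign) else FixedDesign(X)
    k = C.shape[1]
    design1 = FixedDesign(
        np.column_stack([design0.X, g_cells[:, None] * C]),
        design0.names + [f"ixn_{j}" for j in range(k)],
    )
    terms = [RSigma, Sigma]
    warm = None
    if fit is not None:
        warm = [
            np.maximum(
                [
                    fit.variances.get("relatedness_x_context", 0.1),
                    fit.variances.get("context", 0.1),
                    fit.variances.get("noise", 0.5),
                ],
                1e-6,
            )
        ]
    null = fit_variance_components(
        y, design0, terms, method="ml", starts=warm, n_starts=n_starts
    )
    warm_alt = [
        np.maximum(
            [
                null.variances["relatedness_x_context"],
                null.variances["context"],
                null.variances["noise"],
            ],
            1e-6,
        )
    ]
    alt = fit_variance_components(y, design1, terms, method="ml", starts=warm_alt)
    stat = max(2.0 * (alt.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(stat, df=k))


def interaction_test_no_relatedness(
    y,
    g,
    X: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    gene_id: str = "gene",
    variant_id: str = "variant",
    n_starts: int = 3,
) -> GxcResult:
    """The score test with the donor-repeat (R*Sigma) term removed from the null.

    This is the population-cohort variant of the model; with many cells per
    donor it yields inflated statistics and exists for benchmarking.
    """
    y = _as_values(y)
    g_cells = _as_cells(g)
    _check_nonconstant(g_cells)
    fit = fit_variance_components(y, X, [Sigma], method="reml", n_starts=n_starts)
    F = g_cells[:, None] * Sigma.factor
    return _score_test(fit, F, gene_id, variant_id)
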