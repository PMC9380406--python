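"""Per-cell allelic effect estimation (posterior means of the GxC random effect)
and downstream cell-stratification utilities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from scgxc.covariance import LowRankCovariance, gxc_covariance
from scgxc.null_model import FixedDesign, NullFit, fit_variance_components
from scgxc.preprocessing import DegenerateInputError, ExpressionVector, GenotypeVector

__all__ = ["EffectProfile", "estimate_effects", "flag_opposite_effects", "stratify_by_effect"]


@dataclass
class EffectProfile:
    """Persistent effect plus per-cell GxC effect estimates for one gene-variant pair."""

    beta_G: float
    beta_GxC: np.ndarray
    sigma2_GxC: float
    variances: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        """Per-cell total allelic effect ``beta_G + beta_GxC_i``."""
        return self.beta_G + self.beta_GxC

    @property
    def n_cells(self) -> int:
        return self.beta_GxC.shape[0]


def estimate_effects(
    y,
    g,
    X: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    null_fit: NullFit | None = None,
    n_starts: int = 3,
) -> EffectProfile:
    """Estimate the persistent effect and per-cell GxC effects for one pair.

    The alternative model (null terms plus the ``diag(g) Sigma diag(g)``
    component) is fitted by REML, warm-started from the null variance
    components when a null fit is supplied.  The per-cell effects are the
    posterior mean of the GxC random effect,
    ``sigma2_GxC * Sigma diag(g) K^{-1} (y - X beta)``, evaluated through the
    low-rank factors.
    """
    y = y.values if isinstance(y, ExpressionVector) else np.asarray(y, dtype=float)
    g_cells = g.expanded if isinstance(g, GenotypeVector) else np.asarray(g, dtype=float)
    if np.allclose(g_cells, g_cells[0]):
        raise DegenerateInputError("genotype is constant across cells: unestimable")
    design = X if isinstance(X, FixedDesign) else FixedDesign(X)
    if "genotype" in design.names:
        g_idx = design.names.index("genotype")
    else:
        matches = [
            j for j in range(design.p) if np.array_equal(design.X[:, j], g_cells)
        ]
        if matches:
            g_idx = matches[0]
        else:
            design = design.with_column(g_cells, "genotype")
            g_idx = design.p - 1
    Ggxc = gxc_covariance(g_cells, _as_context(Sigma))
    terms = [RSigma, Sigma, Ggxc]
    starts = None
    if null_fit is not None:
        v = null_fit.variances
        warm = np.array(
            [
                max(v.get(RSigma.description or "term_0", 0.1), 1e-4),
                max(v.get(Sigma.description or "term_1", 0.1), 1e-4),
                0.01,
                max(v.get("noise", 0.5), 1e-4),
            ]
        )
        starts = [warm]
    fit = fit_variance_components(
        y, design, terms, method="reml", starts=starts, n_starts=n_starts
    )
    sigma2_gxc = fit.variances.get("gxc", 0.0)
    beta_G = float(fit.beta[g_idx])
    if sigma2_gxc == 0.0:
        b = np.zeros(y.shape[0])
    else:
        t = fit.solve(fit.residual)
        C = Sigma.factor
        b = sigma2_gxc * (C @ (C.T @ (g_cells * t)))
    return EffectProfile(
        beta_G=beta_G, beta_GxC=b, sigma2_GxC=float(sigma2_gxc), variances=fit.variances
    )


def _as_context(Sigma: LowRankCovariance):
    from scgxc.preprocessing import ContextMatrix

    return ContextMatrix(Sigma.factor, standardized=True)


def flag_opposite_effects(
    profile: EffectProfile, threshold: float = 0.25, mode: str = "total"
) -> tuple[bool, float]:
    """Flag pairs where a large share of cells has effects opposing the persistent one.

    ``mode="total"`` (default) counts cells whose total effect
    ``beta_G + beta_GxC_i`` has the opposite sign to ``beta_G``; sign(0) is
    treated as the sign of ``beta_G`` (non-opposite).  ``mode="gxc"`` counts
    opposite signs in the GxC portion alone.  Returns ``(flag, fraction)``.
    """
    ref = np.sign(profile.beta_G)
    if ref == 0.0:
        warnings.warn(
            "persistent effect is exactly 0; using the majority sign of the "
            "GxC profile as reference",
            stacklevel=2,
        )
        signs = np.sign(profile.beta_GxC)
        ref = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
    if mode == "total":
        values = profile.total
    elif mode == "gxc":
        values = profile.beta_GxC
    else:
        raise ValueError("mode must be 'total' or 'gxc'")
    opposite = np.sign(values) == -ref
    fraction = float(opposite.mean())
    return fraction >= threshold, fraction


def stratify_by_effect(
    profile: EffectProfile, q: float = 0.3, mode: str = "absolute"
) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of the top and bottom ``q``-quantile cells by GxC effect.

    Ranking is by ``|beta_GxC|`` (``mode="absolute"``) or by the signed value;
    each returned set has exactly ``floor(q * N)`` cells and ties are broken
    by cell order (stable sort), so the split is deterministic.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    if mode == "absolute":
        key = np.abs(profile.beta_GxC)
    elif mode == "signed":
        key = profile.beta_GxC
    else:
        raise ValueError("mode must be 'absolute' or 'signed'")
    if np.allclose(key, key[0]):
        warnings.warn("effect profile is constant; stratification is arbitrary", stacklevel=2)
    n_q = int(np.floor(q * key.shape[0]))
    order = np.argsort(key, kind="stable")
    bottom = np.sort(order[:n_q])
    top = np.sort(order[key.shape[0] - n_q :])
    return top, bottom
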