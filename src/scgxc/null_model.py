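"""Variance-component fitting for the background (null) mixed model.

The marginal covariance is ``K = v_RC * W_RC W_RC' + v_C * Sigma + v_n * I``
(plus, for the alternative model used in effect estimation, a GxC term).
Fixed effects are profiled out by GLS and the (restricted) log-likelihood is
maximized over log-variances with a quasi-Newton method and analytic
gradients.  All per-iteration work is ``O(r^3)`` on cached cross-products of
the stacked factor matrix -- nothing of size N is touched inside the
optimizer loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from scgxc.covariance import (
    CompositeCovariance,
    LowRankCovariance,
    cholesky_with_jitter,
)
from scgxc.preprocessing import ExpressionVector

__all__ = [
    "FixedDesign",
    "NullFit",
    "GramKernel",
    "fit_null",
    "fit_variance_components",
    "profile_loglik",
]

_ZERO_TOL = 1e-8  # variances below this are reported as exactly 0
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FixedDesign:
    """Fixed-effect design matrix; the first column is expected to be the intercept."""

    X: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def with_column(self, col: np.ndarray, name: str) -> "FixedDesign":
        return FixedDesign(np.column_stack([self.X, col]), self.names + [name])


class GramKernel:
    """Cached cross-products enabling O(r^3) likelihood evaluations.

    ``blocks`` are the unscaled factors of the low-rank covariance terms, in a
    fixed order; the model covariance is
    ``K = sum_t v_t * W_t W_t' + v_noise * I``.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
        self.n = self.y.shape[0]
        self.p = self.X.shape[1]
        widths = [b.shape[1] for b in self.blocks]
        self.slices = []
        start = 0
        for w in widths:
            self.slices.append(slice(start, start + w))
            start += w
        self.r = start
        W = np.hstack(self.blocks) if self.blocks else np.zeros((self.n, 0))
        self.G = W.T @ W
        self.Wty = W.T @ self.y
        self.WtX = W.T @ self.X
        self.yty = float(self.y @ self.y)
        self.Xty = self.X.T @ self.y
        self.XtX = self.X.T @ self.X
        sign, self.logdet_XtX = np.linalg.slogdet(self.XtX)
        if sign <= 0:
            raise ValueError("fixed-effect design is rank deficient")

    # -- core Woodbury pieces ------------------------------------------------

    def _pieces(self, scales: np.ndarray, noise: float) -> dict:
        s = np.concatenate(
            [np.full(sl.stop - sl.start, np.sqrt(v)) for sl, v in zip(self.slices, scales)]
        ) if self.r else np.zeros(0)
        Gds = self.G * s[None, :]        # G @ diag(s)
        Gs = Gds * s[:, None]            # diag(s) @ G @ diag(s)
        M = np.eye(self.r) + Gs / noise
        L = cholesky_with_jitter(M, label="Woodbury capacitance")
        logdet_K = self.n * np.log(noise) + 2.0 * float(np.sum(np.log(np.diag(L))))

        def minv(B):
            return linalg.cho_solve((L, True), B)

        a_y = s * self.Wty               # diag(s) W' y
        A_X = s[:, None] * self.WtX      # diag(s) W' X
        MiA_X = minv(A_X)
        Mia_y = minv(a_y)
        XtKiX = (self.XtX - A_X.T @ MiA_X / noise) / noise
        XtKiy = (self.Xty - A_X.T @ Mia_y / noise) / noise
        ytKiy = (self.yty - a_y @ Mia_y / noise) / noise
        LB = cholesky_with_jitter(XtKiX, label="X' K^-1 X")
        beta = linalg.cho_solve((LB, True), XtKiy)
        rKr = ytKiy - float(XtKiy @ beta)
        logdet_B = 2.0 * float(np.sum(np.log(np.diag(LB))))
        return {
            "s": s, "Gds": Gds, "Gs": Gs, "L": L, "minv": minv,
            "logdet_K": logdet_K, "beta": beta, "rKr": rKr,
            "XtKiX": XtKiX, "XtKiy": XtKiy, "LB": LB, "logdet_B": logdet_B,
            "a_y": a_y, "A_X": A_X, "MiA_X": MiA_X, "Mia_y": Mia_y,
        }

    def loglik(self, scales, noise: float, reml: bool = True) -> float:
        pc = self._pieces(np.asarray(scales, dtype=float), float(noise))
        if reml:
            return -0.5 * (
                (self.n - self.p) * _LOG2PI
                + pc["logdet_K"] + pc["logdet_B"] - self.logdet_XtX + pc["rKr"]
            )
        return -0.5 * (self.n * _LOG2PI + pc["logdet_K"] + pc["rKr"])

    def loglik_and_grad(
        self, scales, noise: float, reml: bool = True
    ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient w.r.t. (scales..., noise)."""
        scales = np.asarray(scales, dtype=float)
        noise = float(noise)
        pc = self._pieces(scales, noise)
        s, Gds, Gs, minv = pc["s"], pc["Gds"], pc["Gs"], pc["minv"]
        beta = pc["beta"]

        # q = W' K^-1 (y - X beta) through cached cross-products
        c_r = self.Wty - self.WtX @ beta          # W' r
        a_r = s * c_r                             # diag(s) W' r
        Mia_r = minv(a_r)
        q = (c_r - Gds @ Mia_r / noise) / noise

        # ||K^-1 r||^2 (for the noise derivative)
        rtr = self.yty - 2.0 * float(self.Xty @ beta) + float(beta @ (self.XtX @ beta))
        Kir_sq = (
            rtr - 2.0 * float(a_r @ Mia_r) / noise
            + float(Mia_r @ (Gs @ Mia_r)) / noise**2
        ) / noise**2

        # diag of H = W' K^-1 W
        T1 = minv(Gds.T)                          # M^-1 diag(s) G
        diag_corr = np.einsum("ij,ji->i", Gds, T1)
        diag_H = (np.diag(self.G) - diag_corr / noise) / noise
        tr_Ki = (self.n - float(np.trace(minv(Gs))) / noise) / noise

        # J = X' K^-1 W  (p x r)
        J = (self.WtX.T - pc["MiA_X"].T @ Gds.T / noise) / noise

        grads = np.empty(len(scales) + 1)
        if reml:
            BiJ = linalg.cho_solve((pc["LB"], True), J)
            # X' K^-2 X for the noise REML correction
            XtK2X = (
                self.XtX - 2.0 * pc["A_X"].T @ pc["MiA_X"] / noise
                + pc["MiA_X"].T @ (Gs @ pc["MiA_X"]) / noise**2
            ) / noise**2
            tr_P_noise = tr_Ki - float(
                np.trace(linalg.cho_solve((pc["LB"], True), XtK2X))
            )
        for t, sl in enumerate(self.slices):
            quad = float(q[sl] @ q[sl])
            tr_t = float(np.sum(diag_H[sl]))
            if reml:
                tr_t -= float(np.sum(J[:, sl] * BiJ[:, sl]))
            grads[t] = 0.5 * (quad - tr_t)
        if reml:
            grads[-1] = 0.5 * (Kir_sq - tr_P_noise)
        else:
            grads[-1] = 0.5 * (Kir_sq - tr_Ki)
        if reml:
            ll = -0.5 * (
                (self.n - self.p) * _LOG2PI
                + pc["logdet_K"] + pc["logdet_B"] - self.logdet_XtX + pc["rKr"]
            )
        else:
            ll = -0.5 * (self.n * _LOG2PI + pc["logdet_K"] + pc["rKr"])
        return ll, grads

    def gls_beta(self, scales, noise: float) -> np.ndarray:
        return self._pieces(np.asarray(scales, dtype=float), float(noise))["beta"]


@dataclass
class NullFit:
    """Fitted background model: fixed effects, variances and cached operators."""

    beta: np.ndarray
    variances: dict[str, float]
    loglik: float
    method: str
    kernel: GramKernel
    K0: CompositeCovariance
    X: np.ndarray
    n_starts_used: int = 1
    grad_norm: float = np.nan
    _KiX: np.ndarray | None = field(default=None, repr=False)
    _LB: np.ndarray | None = field(default=None, repr=False)

    @property
    def residual(self) -> np.ndarray:
        return self.kernel.y - self.X @ self.beta

    def solve(self, B: np.ndarray) -> np.ndarray:
        """``K0^{-1} B``."""
        return self.K0.solve(B)

    def project(self, B: np.ndarray) -> np.ndarray:
        """Apply the REML projector ``P0 = K0^-1 - K0^-1 X (X'K0^-1 X)^-1 X'K0^-1``."""
        if self._KiX is None:
            self._KiX = self.K0.solve(self.X)
            self._LB = cholesky_with_jitter(self.X.T @ self._KiX, label="X' K^-1 X")
        KiB = self.K0.solve(B)
        return KiB - self._KiX @ linalg.cho_solve((self._LB, True), self.X.T @ KiB)


def _default_starts(y: np.ndarray, X: np.ndarray, n_terms: int) -> list[np.ndarray]:
    """Multi-start grid over (term variances..., noise), on the raw scale."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = max(float(np.var(y - X @ beta_ols)), 1e-6)
    total = n_terms + 1
    starts = [np.full(total, v0 / total)]
    noise_dom = np.full(total, 0.05 * v0 / max(n_terms, 1))
    noise_dom[-1] = 0.9 * v0
    starts.append(noise_dom)
    ctx_dom = np.full(total, 0.9 * v0 / max(n_terms, 1))
    ctx_dom[-1] = 0.1 * v0
    starts.append(ctx_dom)
    return starts


def fit_variance_components(
    y: np.ndarray,
    X: FixedDesign | np.ndarray,
    terms: list[LowRankCovariance],
    method: str = "reml",
    starts: list[np.ndarray] | None = None,
    n_starts: int = 3,
    gtol: float = 1e-4,
) -> NullFit:
    """Maximize the (restricted) likelihood over the variance scales of ``terms`` + noise.

    ``starts`` overrides the default 3-start grid; pass a single start for
    fast simulation loops.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    design = X if isinstance(X, FixedDesign) else FixedDesign(X)
    if design.n <= design.p + 3:
        raise ValueError("too few cells relative to fixed effects")
    kernel = GramKernel(y, design.X, [t.factor for t in terms])
    reml = method == "reml"

    def negloglik(theta):
        v = np.exp(theta)
        ll, g = kernel.loglik_and_grad(v[:-1], v[-1], reml=reml)
        return -ll, -g * v  # chain rule for log-parameterization

    if starts is None:
        starts = _default_starts(kernel.y, design.X, len(terms))[:n_starts]
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            negloglik,
            np.log(np.maximum(np.asarray(x0, dtype=float), 1e-10)),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 12.0)] * (len(terms) + 1),
            options={"maxiter": 300, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-component optimization failed for all starts")
    v = np.exp(best.x)
    v[v < _ZERO_TOL] = 0.0
    scales, noise = v[:-1], max(v[-1], _ZERO_TOL)
    beta = kernel.gls_beta(scales, noise)
    ll = kernel.loglik(scales, noise, reml=reml)
    fitted_terms = [t.with_scale(vi) for t, vi in zip(terms, scales)]
    K0 = CompositeCovariance(fitted_terms, noise)
    names = [t.description or f"term_{i}" for i, t in enumerate(terms)]
    variances = {name: float(vi) for name, vi in zip(names, scales)}
    variances["noise"] = float(noise)
    return NullFit(
        beta=beta,
        variances=variances,
        loglik=float(ll),
        method=method,
        kernel=kernel,
        K0=K0,
        X=design.X,
        n_starts_used=n_used,
        grad_norm=float(np.max(np.abs(best.jac))),
    )


def fit_null(
    y: ExpressionVector | np.ndarray,
    X: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    method: str = "reml",
    **kwargs,
) -> NullFit:
    """Fit the interaction-test null model ``K = v_RC R*Sigma + v_C Sigma + v_n I``.

    ``y`` should be gaussianized expression; the genotype (if testing for
    interactions) must already be a column of ``X``.
    """
    if isinstance(y, ExpressionVector):
        if y.state != "gaussianized":
            raise ValueError("expression must be gaussianized before fitting")
        y = y.values
    return fit_variance_components(y, X, [RSigma, Sigma], method=method, **kwargs)


def profile_loglik(
    y: np.ndarray,
    X: FixedDesign | np.ndarray,
    Sigma: LowRankCovariance,
    RSigma: LowRankCovariance,
    variances,
    method: str = "reml",
) -> float:
    """(Restricted) log-likelihood at fixed ``(v_RC, v_C, v_noise)`` with beta profiled by GLS."""
    v = np.asarray(variances, dtype=float)
    if v.shape != (3,) or (v < 0).any() or not v.any():
        raise ValueError("variances must be 3 nonnegative values, not all zero")
    if isinstance(y, ExpressionVector):
        y = y.values
    design = X if isinstance(X, FixedDesign) else FixedDesign(X)
    kernel = GramKernel(y, design.X, [RSigma.factor, Sigma.factor])
    return float(kernel.loglik(v[:2], max(v[2], 1e-12), reml=(method == "reml")))
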