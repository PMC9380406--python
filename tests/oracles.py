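"""Brute-force dense-matrix reference implementations used only by the tests.

Everything here materializes N x N covariance matrices and uses plain
inversions, deliberately independent of the package's low-rank code paths.
"""

from __future__ import annotations

import numpy as np


def dense_loglik(y, X, K, reml=True):
    """(Restricted) Gaussian log-likelihood with beta profiled out by GLS."""
    n, p = X.shape
    Ki = np.linalg.inv(K)
    B = X.T @ Ki @ X
    beta = np.linalg.solve(B, X.T @ Ki @ y)
    r = y - X @ beta
    _, ldK = np.linalg.slogdet(K)
    rKr = r @ Ki @ r
    if reml:
        _, ldB = np.linalg.slogdet(B)
        _, ldX = np.linalg.slogdet(X.T @ X)
        return -0.5 * ((n - p) * np.log(2 * np.pi) + ldK + ldB - ldX + rKr)
    return -0.5 * (n * np.log(2 * np.pi) + ldK + rKr)


def dense_projector(X, K):
    """P0 = K^-1 - K^-1 X (X'K^-1 X)^-1 X'K^-1."""
    Ki = np.linalg.inv(K)
    KiX = Ki @ X
    return Ki - KiX @ np.linalg.solve(X.T @ KiX, KiX.T)


def dense_score_test(y, X, K0, F):
    """Score statistic and mixture weights computed with dense matrices."""
    Ki = np.linalg.inv(K0)
    B = X.T @ Ki @ X
    beta = np.linalg.solve(B, X.T @ Ki @ y)
    r = y - X @ beta
    half = F.T @ Ki @ r
    Q = 0.5 * float(half @ half)
    P0 = dense_projector(X, K0)
    S = 0.5 * F.T @ P0 @ F
    lam = np.linalg.eigvalsh(0.5 * (S + S.T))
    return Q, lam[lam > 1e-12 * max(lam.max(), 1e-12)]


def dense_blup(y, X, K, g, C, v_gxc):
    """Posterior mean of the GxC random effect via the dense conditional-mean formula."""
    Ki = np.linalg.inv(K)
    B = X.T @ Ki @ X
    beta = np.linalg.solve(B, X.T @ Ki @ y)
    r = y - X @ beta
    Sigma = C @ C.T
    return v_gxc * Sigma @ np.diag(g) @ Ki @ r


def dense_hadamard(R, S):
    return R * S


def dense_relatedness(assignment, kinship=None):
    """Cell-level relatedness matrix R expanded from the donor assignment."""
    n = len(assignment)
    d = int(np.max(assignment)) + 1
    Z = np.zeros((n, d))
    Z[np.arange(n), assignment] = 1.0
    if kinship is None:
        kinship = np.eye(d)
    return Z @ kinship @ Z.T
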