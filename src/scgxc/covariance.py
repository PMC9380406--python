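"""Factored (low-rank + diagonal) covariance algebra.

Every covariance term of the model is represented as ``scale * W @ W.T`` with
a tall-skinny factor ``W``; composite covariances add an iid noise diagonal.
Solves and log-determinants go through the Woodbury identity and the matrix
determinant lemma, so the cost is ``O(N * r^2 + r^3)`` for total factor rank
``r`` -- linear in the number of cells ``N``.  Dense N x N realizations only
exist in the test-suite oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from scgxc.preprocessing import CellDonorMap, ContextMatrix, GenotypeVector

__all__ = [
    "LowRankCovariance",
    "CompositeCovariance",
    "context_covariance",
    "relatedness_context_covariance",
    "gxc_covariance",
    "solve_and_logdet",
    "cholesky_with_jitter",
]

_JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)


def cholesky_with_jitter(A: np.ndarray, label: str = "matrix") -> np.ndarray:
    """Lower Cholesky factor, retrying with a small diagonal jitter.

    Standardized contexts can make the inner matrices near-singular; we walk
    a jitter ladder up to 1e-6 (relative to the mean diagonal) before failing.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        return A.reshape(0, 0)
    scale = max(np.mean(np.diag(A)), 1.0)
    for jit in _JITTER_LADDER:
        try:
            return linalg.cholesky(A + jit * scale * np.eye(A.shape[0]), lower=True)
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError(
        f"{label} is not positive definite even after jitter 1e-6; "
        "check for duplicated contexts or add noise"
    )


@dataclass
class LowRankCovariance:
    """``scale * factor @ factor.T`` for a tall N x r factor."""

    factor: np.ndarray
    scale: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        self.factor = np.atleast_2d(np.asarray(self.factor, dtype=float))
        if self.scale < 0:
            raise ValueError("covariance scale must be nonnegative")

    @property
    def n(self) -> int:
        return self.factor.shape[0]

    @property
    def rank(self) -> int:
        return self.factor.shape[1]

    def dense(self) -> np.ndarray:
        return self.scale * self.factor @ self.factor.T

    def with_scale(self, scale: float) -> "LowRankCovariance":
        return LowRankCovariance(self.factor, scale, self.description)


@dataclass
class CompositeCovariance:
    """Sum of low-rank terms plus ``noise * I``, with cached Woodbury pieces."""

    terms: list[LowRankCovariance]
    noise: float
    _chol: np.ndarray | None = field(default=None, repr=False)
    _stack: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.noise <= 0:
            raise ValueError(
                "composite covariance requires noise > 0 for the Woodbury route"
            )
        if not self.terms:
            raise ValueError("at least one low-rank term (possibly scale 0) required")
        ns = {t.n for t in self.terms}
        if len(ns) != 1:
            raise ValueError("all terms must share the same number of cells")

    @property
    def n(self) -> int:
        return self.terms[0].n

    def _factorize(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked scaled factor U and chol of the capacitance I + U'U / noise."""
        if self._chol is None:
            blocks = [np.sqrt(t.scale) * t.factor for t in self.terms if t.scale > 0]
            if blocks:
                U = np.hstack(blocks)
            else:
                U = np.zeros((self.n, 0))
            M = np.eye(U.shape[1]) + (U.T @ U) / self.noise
            self._stack = U
            self._chol = cholesky_with_jitter(M, label="Woodbury capacitance")
        return self._stack, self._chol

    def solve(self, B: np.ndarray) -> np.ndarray:
        """``K^{-1} B`` for a vector or N x m matrix B."""
        U, L = self._factorize()
        B = np.asarray(B, dtype=float)
        if U.shape[1] == 0:
            return B / self.noise
        UtB = U.T @ B
        inner = linalg.cho_solve((L, True), UtB)
        return (B - U @ inner / self.noise) / self.noise

    def logdet(self) -> float:
        U, L = self._factorize()
        return self.n * np.log(self.noise) + 2.0 * float(np.sum(np.log(np.diag(L))))

    def quad(self, a: np.ndarray, b: np.ndarray | None = None) -> float:
        """Quadratic form ``a' K^{-1} b`` (b defaults to a)."""
        if b is None:
            b = a
        return float(a @ self.solve(b))

    def dense(self) -> np.ndarray:
        K = self.noise * np.eye(self.n)
        for t in self.terms:
            K += t.dense()
        return K


def context_covariance(C: ContextMatrix, scale: float = 1.0) -> LowRankCovariance:
    """``Sigma = C @ C.T`` from a standardized context matrix."""
    if not C.standardized:
        raise ValueError("contexts must be standardized before building Sigma")
    return LowRankCovariance(C.values, scale, description="context")


def relatedness_context_covariance(
    cell_map: CellDonorMap,
    C: ContextMatrix,
    kinship: np.ndarray | None = None,
    scale: float = 1.0,
) -> LowRankCovariance:
    """Factor of the Hadamard product ``R (*) Sigma`` (donor repeat x context).

    With ``R = A @ A.T`` (A the cell-donor indicator times the Cholesky of the
    donor kinship) and ``Sigma = C @ C.T``, the Hadamard product factors as
    ``W @ W.T`` where the columns of W are all products ``a_i * c_j``.  With
    no kinship supplied, donors are treated as unrelated (identity kinship)
    and A is simply the 0/1 indicator.
    """
    if not C.standardized:
        raise ValueError("contexts must be standardized before building R*Sigma")
    Z = cell_map.indicator
    if kinship is None:
        A = Z
    else:
        kinship = np.asarray(kinship, dtype=float)
        if kinship.shape != (cell_map.n_donors, cell_map.n_donors):
            raise ValueError("kinship shape does not match the number of donors")
        if not np.allclose(kinship, kinship.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        A = Z @ cholesky_with_jitter(kinship, label="kinship")
    n, d = A.shape
    k = C.n_contexts
    W = (A[:, :, None] * C.values[:, None, :]).reshape(n, d * k)
    return LowRankCovariance(W, scale, description="relatedness_x_context")


def gxc_covariance(g: GenotypeVector | np.ndarray, C: ContextMatrix, scale: float = 1.0) -> LowRankCovariance:
    """Factor ``diag(g) @ C`` of the GxC covariance ``diag(g) Sigma diag(g)``.

    This is the derivative of the model covariance with respect to the GxC
    variance component, i.e. the kernel the score test evaluates.
    """
    g_cells = g.expanded if isinstance(g, GenotypeVector) else np.asarray(g, dtype=float)
    if g_cells is None:
        raise ValueError("genotype must be expanded to cells first")
    if g_cells.shape[0] != C.n_cells:
        raise ValueError("genotype and context matrix disagree on the number of cells")
    return LowRankCovariance(g_cells[:, None] * C.values, scale, description="gxc")


def solve_and_logdet(K: CompositeCovariance, B: np.ndarray) -> tuple[np.ndarray, float]:
    """``(K^{-1} B, log|K|)`` through the factored representation."""
    return K.solve(B), K.logdet()
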