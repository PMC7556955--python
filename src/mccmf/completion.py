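"""Low-rank representation denoising of similarity matrices.

Solves the convex program

    min_{R,N}  ||R||_* + omega * ||N||_{2,1}   s.t.  D = D R + N

by inexact augmented-Lagrangian alternating-direction updates: the nuclear
norm is handled through a splitting variable X = R and singular value
thresholding, the column-sparse noise N through the L2,1 proximal operator,
and R through a positive-definite linear solve. The completed similarity is
D @ R*, then symmetrised, clipped to [0, 1] and given a unit diagonal so it
can feed the downstream integration and imputation stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._types import SimilarityMatrix

__all__ = [
    "CompletionParams",
    "CompletionResult",
    "svt",
    "l21_shrink",
    "solve_r",
    "lrr_complete",
    "finalize_similarity",
]


@dataclass(frozen=True)
class CompletionParams:
    """Solver parameters.

    omega: weight of the column-sparse noise term, in (0, 1).
    beta0 / rho / beta_max: initial penalty, growth factor per iteration and
        cap of the augmented-Lagrangian penalty beta.
    epsilon: infinity-norm convergence tolerance on both residuals.
    max_iter: iteration cap; exceeding it returns converged=False.
    """

    omega: float = 0.1
    beta0: float = 1e-2
    rho: float = 1.1
    beta_max: float = 1e6
    epsilon: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must be in (0, 1)")
        if self.beta0 <= 0 or self.beta_max <= 0 or self.epsilon <= 0:
            raise ValueError("beta0, beta_max and epsilon must be positive")
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class CompletionResult:
    R_star: np.ndarray
    N_star: np.ndarray
    completed: np.ndarray
    iterations: int
    residual_constraint: float  # ||D - D R - N||_inf
    residual_split: float  # ||R - X||_inf
    converged: bool
    objective: float = 0.0
    residual_trace: list = field(default_factory=list)


def _check_finite(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError(f"{name} contains non-finite entries")
    return M


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: proximal operator of ``tau * ||.||_*``.

    Soft-thresholds the singular values of M by tau.
    """
    M = _check_finite(M, "M")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0.0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def l21_shrink(Q: np.ndarray, tau: float) -> np.ndarray:
    """Column-wise shrinkage: proximal operator of ``tau * ||.||_{2,1}``.

    Each column q becomes ``max(0, 1 - tau/||q||) * q``; columns with norm at
    most tau are annihilated.
    """
    Q = _check_finite(Q, "Q")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0.0:
        return Q.copy()
    norms = np.linalg.norm(Q, axis=0)
    scale = np.zeros_like(norms)
    nz = norms > tau
    scale[nz] = 1.0 - tau / norms[nz]
    return Q * scale[None, :]


def solve_r(
    D: np.ndarray,
    N: np.ndarray,
    X: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    beta: float,
    _cho_factor=None,
) -> np.ndarray:
    """Least-squares update of the representation matrix R.

    Solves (I + D^T D) R = D^T D - D^T N + X + (D^T Y1 - Y2) / beta, the
    stationarity condition of the augmented Lagrangian in R. The system
    matrix is symmetric positive definite for any D.
    """
    D = _check_finite(D, "D")
    rhs = D.T @ D - D.T @ N + X + (D.T @ Y1 - Y2) / beta
    if _cho_factor is None:
        n = D.shape[1]
        _cho_factor = scipy.linalg.cho_factor(np.eye(n) + D.T @ D)
    return scipy.linalg.cho_solve(_cho_factor, rhs)


def nuclear_l21_objective(R: np.ndarray, N: np.ndarray, omega: float) -> float:
    """Objective value ||R||_* + omega * ||N||_{2,1}."""
    return float(
        np.linalg.svd(R, compute_uv=False).sum()
        + omega * np.linalg.norm(N, axis=0).sum()
    )


def lrr_complete(
    D: np.ndarray, params: CompletionParams = CompletionParams()
) -> CompletionResult:
    """Denoise a square similarity matrix by low-rank representation.

    Alternates singular value thresholding (splitting variable X), the linear
    solve for R, and column-wise shrinkage for N, then updates the Lagrange
    multipliers and grows the penalty. Stops when both infinity-norm
    residuals fall below ``params.epsilon``. Hitting ``max_iter`` returns a
    result with ``converged=False`` and a warning rather than an exception.
    """
    D = _check_finite(np.asarray(D, dtype=float), "D")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"D must be square, got shape {D.shape}")
    n = D.shape[0]
    R = np.zeros((n, n))
    X = np.zeros((n, n))
    N = np.zeros((n, n))
    Y1 = np.zeros((n, n))
    Y2 = np.zeros((n, n))
    beta = params.beta0
    cho = scipy.linalg.cho_factor(np.eye(n) + D.T @ D)

    res_c = res_s = np.inf
    trace: list[tuple[float, float]] = []
    it = 0
    for it in range(1, params.max_iter + 1):
        X = svt(R + Y2 / beta, 1.0 / beta)
        R = solve_r(D, N, X, Y1, Y2, beta, _cho_factor=cho)
        DR = D @ R
        N = l21_shrink(D - DR + Y1 / beta, params.omega / beta)
        res_c = float(np.abs(D - DR - N).max())
        res_s = float(np.abs(R - X).max())
        trace.append((res_c, res_s))
        Y1 = Y1 + beta * (D - DR - N)
        Y2 = Y2 + beta * (R - X)
        beta = min(params.rho * beta, params.beta_max)
        if res_c < params.epsilon and res_s < params.epsilon:
            break
    converged = res_c < params.epsilon and res_s < params.epsilon
    if not converged:
        warnings.warn(
            f"LRR completion did not converge in {params.max_iter} iterations "
            f"(residuals {res_c:.2e}, {res_s:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return CompletionResult(
        R_star=R,
        N_star=N,
        completed=D @ R,
        iterations=it,
        residual_constraint=res_c,
        residual_split=res_s,
        converged=converged,
        objective=nuclear_l21_objective(R, N, params.omega),
        residual_trace=trace,
    )


def finalize_similarity(
    result: CompletionResult, ids: list[str], role: str
) -> SimilarityMatrix:
    """Turn a completion result into a valid similarity matrix (role CM or CD).

    The raw product D @ R* need not be symmetric or bounded; it is averaged
    with its transpose, clipped to [0, 1], and given a unit diagonal.
    """
    if role not in {"CM", "CD"}:
        raise ValueError(f"role must be 'CM' or 'CD', got {role!r}")
    C = result.completed
    C = (C + C.T) / 2.0
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(C, list(ids), role)


def complete_similarity(
    sim: SimilarityMatrix, params: CompletionParams = CompletionParams()
) -> tuple[SimilarityMatrix, CompletionResult]:
    """Convenience wrapper: denoise a similarity matrix and post-process."""
    role = {"MF": "CM", "DS": "CD"}.get(sim.role, "CM" if sim.role in {"GM", "IMS", "CM"} else "CD")
    result = lrr_complete(sim.values, params)
    return finalize_similarity(result, sim.ids, role), result
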