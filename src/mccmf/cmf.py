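"""Collaborative matrix factorization with similarity regularization.

The (pre-imputed) association matrix PMD is factorized as A @ B.T with latent
dimension k, minimising

    ||PMD - A B^T||_F^2 + lambda_l (||A||_F^2 + ||B||_F^2)
        + lambda_m ||IMS - A A^T||_F^2 + lambda_d ||IDS - B B^T||_F^2,

so that the latent representations of similar miRNAs (resp. diseases) are
pushed towards each other through their integrated similarity matrices.
Factors are initialised from the top-k SVD of PMD and refined by alternating
fixed-point updates derived from the stationarity conditions; each update
solves a k x k symmetric positive-definite system. The procedure is fully
deterministic: the only nondeterminism in an SVD is a sign convention, which
is fixed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg

from ._types import PredictionMatrix, SimilarityMatrix

__all__ = [
    "CmfParams",
    "CMFModel",
    "DEFAULT_LAMBDA_L_GRID",
    "DEFAULT_LAMBDA_MD_GRID",
    "svd_init",
    "cmf_objective",
    "update_A",
    "update_B",
    "fit_cmf",
    "predict_scores",
    "grid_search",
]

DEFAULT_LAMBDA_L_GRID: tuple[float, ...] = (2.0**-2, 2.0**-1, 1.0, 2.0)
DEFAULT_LAMBDA_MD_GRID: tuple[float, ...] = tuple(2.0**p for p in range(-3, 6))


@dataclass(frozen=True)
class CmfParams:
    """Hyperparameters of the collaborative factorization.

    k: latent dimension (clamped to min(nm, nd) at fit time).
    lambda_l: Tikhonov weight on both factor matrices.
    lambda_m / lambda_d: weights tying A A^T to IMS and B B^T to IDS.
    max_iter / tol: sweep cap and relative-objective-change stopping rule.
    seed: reserved; the algorithm itself is deterministic.
    """

    k: int = 50
    lambda_l: float = 0.25
    lambda_m: float = 0.125
    lambda_d: float = 0.125
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.lambda_l, self.lambda_m, self.lambda_d) < 0:
            raise ValueError("lambda parameters must be nonnegative")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass
class CMFModel:
    A: np.ndarray  # nm x k
    B: np.ndarray  # nd x k
    params: CmfParams
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    mirna_ids: list[str] | None = None
    disease_ids: list[str] | None = None


def _fix_svd_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # force the largest-magnitude entry of each left singular vector positive
    signs = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def svd_init(pmd: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Initial factors from the top-k SVD: A = U sqrt(S_k), B = V sqrt(S_k).

    A @ B.T is then the best rank-k approximation of PMD.
    """
    pmd = np.asarray(pmd, dtype=float)
    if not 1 <= k <= min(pmd.shape):
        raise ValueError(f"k={k} out of range for shape {pmd.shape}")
    U, s, Vt = np.linalg.svd(pmd, full_matrices=False)
    U, Vt = _fix_svd_signs(U[:, :k], Vt[:k])
    root = np.sqrt(s[:k])
    return U * root, Vt.T * root


def cmf_objective(
    pmd: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    ims: np.ndarray,
    ids: np.ndarray,
    params: CmfParams,
) -> float:
    """Value of the regularized factorization objective."""
    fit = np.linalg.norm(pmd - A @ B.T, "fro") ** 2
    ridge = params.lambda_l * (
        np.linalg.norm(A, "fro") ** 2 + np.linalg.norm(B, "fro") ** 2
    )
    sim_m = params.lambda_m * np.linalg.norm(ims - A @ A.T, "fro") ** 2
    sim_d = params.lambda_d * np.linalg.norm(ids - B @ B.T, "fro") ** 2
    return float(fit + ridge + sim_m + sim_d)


def _spd_solve_right(M: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Solve X G = M for X with G symmetric positive definite."""
    c = scipy.linalg.cho_factor((G + G.T) / 2.0)
    return scipy.linalg.cho_solve(c, M.T).T


def update_A(
    pmd: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    ims: np.ndarray,
    params: CmfParams,
) -> np.ndarray:
    """Fixed-point update of the miRNA factors.

    A' = (PMD B + 2 lambda_m IMS A)(B^T B + lambda_l I + 2 lambda_m A^T A)^{-1},
    with the incoming A on both sides. This is the exact stationarity
    condition dL/dA = 0 of the objective (the similarity penalty contributes
    a factor 2 on differentiation), so a fixed point of the map is a
    stationary point. The k x k Gram system is solved via a Cholesky
    factorization, never inverted explicitly.
    """
    k = A.shape[1]
    lam2 = 2.0 * params.lambda_m
    gram = B.T @ B + params.lambda_l * np.eye(k) + lam2 * (A.T @ A)
    rhs = pmd @ B + lam2 * (ims @ A)
    return _spd_solve_right(rhs, gram)


def update_B(
    pmd: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    ids: np.ndarray,
    params: CmfParams,
) -> np.ndarray:
    """Mirror of :func:`update_A` for the disease factors (PMD^T, IDS, lambda_d)."""
    k = B.shape[1]
    lam2 = 2.0 * params.lambda_d
    gram = A.T @ A + params.lambda_l * np.eye(k) + lam2 * (B.T @ B)
    rhs = pmd.T @ A + lam2 * (ids @ B)
    return _spd_solve_right(rhs, gram)


def fit_cmf(
    pmd: np.ndarray,
    ims: SimilarityMatrix | np.ndarray,
    ids: SimilarityMatrix | np.ndarray,
    params: CmfParams = CmfParams(),
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> CMFModel:
    """Fit the collaborative factorization by alternating updates.

    Records the objective after every sweep and stops when its relative
    change drops below ``params.tol`` or after ``params.max_iter`` sweeps.
    Deterministic for identical inputs.
    """
    pmd = np.asarray(pmd, dtype=float)
    if isinstance(ims, SimilarityMatrix):
        mirna_ids = mirna_ids or list(ims.ids)
        ims = ims.values
    if isinstance(ids, SimilarityMatrix):
        disease_ids = disease_ids or list(ids.ids)
        ids = ids.values
    k = min(params.k, min(pmd.shape))
    if k != params.k:
        params = replace(params, k=k)
    A, B = svd_init(pmd, k)
    trace = [cmf_objective(pmd, A, B, ims, ids, params)]
    converged = False
    sweep = 0
    for sweep in range(1, params.max_iter + 1):
        A = update_A(pmd, A, B, ims, params)
        B = update_B(pmd, A, B, ids, params)
        obj = cmf_objective(pmd, A, B, ims, ids, params)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"CMF objective diverged at sweep {sweep}"
            )
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= params.tol * max(1.0, abs(prev)):
            converged = True
            break
    return CMFModel(
        A=A,
        B=B,
        params=params,
        objective_trace=trace,
        n_iter=sweep,
        converged=converged,
        mirna_ids=mirna_ids,
        disease_ids=disease_ids,
    )


def predict_scores(model: CMFModel) -> PredictionMatrix:
    """Score every miRNA-disease pair as A @ B.T."""
    scores = model.A @ model.B.T
    nm, nd = scores.shape
    mirnas = model.mirna_ids or [f"m{i}" for i in range(nm)]
    diseases = model.disease_ids or [f"d{j}" for j in range(nd)]
    return PredictionMatrix(scores, list(mirnas), list(diseases))


def cmf_gradients(
    pmd: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    ims: np.ndarray,
    ids: np.ndarray,
    params: CmfParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the objective w.r.t. A and B."""
    E = A @ B.T - pmd
    gA = 2.0 * (
        E @ B
        + params.lambda_l * A
        + 2.0 * params.lambda_m * (A @ A.T - ims) @ A
    )
    gB = 2.0 * (
        E.T @ A
        + params.lambda_l * B
        + 2.0 * params.lambda_d * (B @ B.T - ids) @ B
    )
    return gA, gB


def grid_search(
    md,
    mf: SimilarityMatrix,
    ds: SimilarityMatrix,
    grid_l: Sequence[float] = DEFAULT_LAMBDA_L_GRID,
    grid_md: Sequence[float] | None = None,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    base_params: CmfParams = CmfParams(),
    untied: bool = False,
    pipeline_config=None,
):
    """Select (lambda_l, lambda_m=lambda_d) by pairs-mode cross-validated AUC.

    Runs the evaluation module's cross-validation for every grid cell and
    returns ``(best CmfParams, table)`` where the table rows are
    ``(lambda_l, lambda_m, lambda_d, mean_auc)``. Ties prefer the smallest
    lambdas. ``untied=True`` searches the full lambda_m x lambda_d product.
    """
    from .evaluation import make_cv_plan, run_cv
    from .pipeline import RunConfig

    grid_l = list(grid_l)
    grid_md = list(grid_md if grid_md is not None else DEFAULT_LAMBDA_MD_GRID)
    if not grid_l or not grid_md:
        raise ValueError("empty hyperparameter grid")
    cells: list[tuple[float, float, float]] = []
    if untied:
        cells = [(l, m, d) for l in grid_l for m in grid_md for d in grid_md]
    else:
        cells = [(l, s, s) for l in grid_l for s in grid_md]
    plan = make_cv_plan(md, folds=folds, repeats=repeats, seed=seed)
    config = pipeline_config or RunConfig()
    rows = []
    best = None
    for lam_l, lam_m, lam_d in cells:
        params = replace(base_params, lambda_l=lam_l, lambda_m=lam_m, lambda_d=lam_d)
        cell_config = replace(config, cmf=params)
        report = run_cv(md, mf, ds, cell_config, plan)
        rows.append((lam_l, lam_m, lam_d, report.auc_mean))
        key = (-report.auc_mean, lam_l, lam_m, lam_d)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1], rows
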