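"""Similarity integration and WKNKN pre-imputation of the association matrix.

Integration blends, entrywise, the completed similarity, the GIP kernel and
the original similarity: where the original entry is zero (no semantic
information) the completed and GIP values are averaged; elsewhere all three
are averaged.

WKNKN (weighted K nearest known neighbors) replaces unknown zeros of the
binary association matrix with a similarity-weighted, geometrically decayed
average over each entity's K most similar neighbors that have at least one
known association, done from the miRNA side and the disease side, averaged,
and finally combined with the original matrix by an entrywise maximum so
known associations are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._types import AssociationMatrix, SimilarityMatrix

__all__ = ["WknknParams", "ImputedAssociation", "integrate_similarity", "wknkn"]


@dataclass(frozen=True)
class WknknParams:
    """K: neighbor count (default 5); eta: decay weight in (0, 1], default 0.7."""

    K: int = 5
    eta: float = 0.7

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must be in (0, 1]")


@dataclass
class ImputedAssociation:
    """Pre-processed association matrix PMD: real values in [0, 1], >= MD."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]


def integrate_similarity(
    completed: SimilarityMatrix,
    gip: SimilarityMatrix,
    original: SimilarityMatrix,
) -> SimilarityMatrix:
    """Fuse completed, GIP and original similarities entrywise.

    Output role is IMS when the inputs are miRNA-side (CM/GM/MF), IDS for
    disease-side (CD/GD/DS).
    """
    for other in (gip, original):
        if other.ids != completed.ids:
            raise ValueError("similarity matrices carry different labels")
    C, G, S = completed.values, gip.values, original.values
    fused = np.where(S == 0.0, (C + G) / 2.0, (C + G + S) / 3.0)
    role = "IMS" if completed.role in {"CM", "GM", "MF"} else "IDS"
    return SimilarityMatrix(fused, list(completed.ids), role)


def _neighbor_estimate(
    md: np.ndarray, sim: np.ndarray, labels: list[str], params: WknknParams
) -> np.ndarray:
    """Row-side WKNKN estimate: for each row i, a decayed weighted average of
    the MD rows of the K most similar other rows with >= 1 known association."""
    n = md.shape[0]
    known = md.sum(axis=1) > 0
    est = np.zeros_like(md, dtype=float)
    short = False
    for i in range(n):
        cand = [j for j in range(n) if j != i and known[j]]
        if not cand:
            continue
        # descending similarity; equal similarities broken by label
        cand.sort(key=lambda j: (-sim[i, j], labels[j]))
        if len(cand) < params.K:
            short = True
        top = cand[: params.K]
        weights = np.array(
            [params.eta**t * sim[i, j] for t, j in enumerate(top)]
        )
        norm = weights.sum()
        if norm == 0.0:
            continue
        est[i] = weights @ md[top] / norm
    if short:
        warnings.warn(
            f"fewer than K={params.K} known neighbors available for some "
            "entities; used all available",
            RuntimeWarning,
            stacklevel=3,
        )
    return est


def wknkn(
    md: AssociationMatrix,
    ims: SimilarityMatrix,
    ids: SimilarityMatrix,
    params: WknknParams = WknknParams(),
) -> ImputedAssociation:
    """Pre-impute unknown entries of MD from its K nearest known neighbors.

    The miRNA-side estimate weights neighbor rows by ``eta^(t-1) * IMS(i, i_t)``
    for the t-th most similar known neighbor; the disease-side estimate is the
    mirror over columns with IDS. PMD = max(MD, (row + col)/2), clipped to
    [0, 1] — known 1-entries always survive.
    """
    if ims.ids != md.mirna_ids:
        raise ValueError("IMS labels do not match MD rows")
    if ids.ids != md.disease_ids:
        raise ValueError("IDS labels do not match MD columns")
    M = md.values.astype(float)
    row_est = _neighbor_estimate(M, ims.values, md.mirna_ids, params)
    col_est = _neighbor_estimate(M.T, ids.values, md.disease_ids, params).T
    pmd = np.maximum(M, (row_est + col_est) / 2.0)
    pmd = np.clip(pmd, 0.0, 1.0)
    return ImputedAssociation(pmd, list(md.mirna_ids), list(md.disease_ids))
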