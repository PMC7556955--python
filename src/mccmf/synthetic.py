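"""Synthetic problem generators with planted low-rank structure.

The generators emulate the statistical structure the predictor assumes:
functionally similar miRNAs associate with semantically similar diseases.
Latent nonnegative factors P (miRNAs) and Q (diseases) define a ground-truth
affinity T = P @ Q.T; the binary association matrix takes the top-density
entries of T, and the two input similarity matrices are the row-cosine
matrices of P and Q plus symmetric noise. Everything is deterministic per
seed, so fixtures are generated at run time rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import AssociationMatrix, DiseaseDAGCollection, SimilarityMatrix

__all__ = [
    "SyntheticConfig",
    "make_problem",
    "make_corrupted_lowrank",
    "make_dag_collection",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale problem dimensions and noise levels.

    nm, nd: numbers of miRNAs and diseases.
    k_true: rank of the planted affinity matrix.
    density: exact fraction of entries set to 1 in the association matrix.
    similarity_noise: standard deviation of the symmetric noise added to the
        cosine similarity matrices.
    corrupt_cols / dag_depth / dag_branching: knobs for the completion and
        semantic-similarity fixtures.
    """

    nm: int = 150
    nd: int = 100
    k_true: int = 5
    density: float = 0.10
    similarity_noise: float = 0.05
    corrupt_cols: int = 0
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 7


def _cosine(P: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(P, axis=1)
    norms[norms == 0] = 1.0
    C = (P / norms[:, None]) @ (P / norms[:, None]).T
    return np.clip(C, -1.0, 1.0)


def _similarity_from_factors(
    P: np.ndarray, noise: float, rng: np.random.Generator, ids: list[str], role: str
) -> SimilarityMatrix:
    C = _cosine(P)
    if noise > 0:
        E = rng.normal(0.0, noise, C.shape)
        C = C + (E + E.T) / 2.0
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(C, ids, role)


def make_problem(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """Generate (MD, MF, DS, ground-truth T) with planted rank-k structure.

    MD is 1 at the top ``density * nm * nd`` entries of T (exact density,
    deterministic per seed). If the thresholding leaves a miRNA or disease
    with no association, the factors are redrawn, up to 10 times.
    """
    rng = np.random.default_rng(config.seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(config.nm)]
    disease_ids = [f"dis-{j:04d}" for j in range(config.nd)]
    n_pos = max(1, int(round(config.density * config.nm * config.nd)))
    for _ in range(10):
        # unit row norms keep entity scales homogeneous so the global
        # top-quantile cut leaves no miRNA or disease without an association
        P = np.abs(rng.normal(size=(config.nm, config.k_true)))
        Q = np.abs(rng.normal(size=(config.nd, config.k_true)))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        Q /= np.linalg.norm(Q, axis=1, keepdims=True)
        T = P @ Q.T
        flat = np.argsort(T, axis=None)[::-1][:n_pos]
        values = np.zeros((config.nm, config.nd), dtype=np.int8)
        values[np.unravel_index(flat, T.shape)] = 1
        if values.sum(axis=1).min() > 0 and values.sum(axis=0).min() > 0:
            md = AssociationMatrix(values, mirna_ids, disease_ids)
            mf = _similarity_from_factors(
                P, config.similarity_noise, rng, mirna_ids, "MF"
            )
            ds = _similarity_from_factors(
                Q, config.similarity_noise, rng, disease_ids, "DS"
            )
            return md, mf, ds, T
    raise ValueError(
        "could not plant a problem where every miRNA and disease has an "
        "association; raise density or shrink the problem"
    )


def make_corrupted_lowrank(
    n: int, rank: int, corrupt_cols: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Exact-rank matrix plus column-sparse corruption.

    ``clean`` is a product of standard-normal factors (numerical rank exactly
    ``rank``); ``corrupted`` replaces ``corrupt_cols`` distinct columns with
    independent noise whose scale matches the clean entries.
    """
    if corrupt_cols > n:
        raise ValueError("cannot corrupt more columns than exist")
    rng = np.random.default_rng(seed)
    clean = rng.normal(size=(n, rank)) @ rng.normal(size=(rank, n))
    corrupted = clean.copy()
    cols = sorted(rng.choice(n, size=corrupt_cols, replace=False).tolist())
    if corrupt_cols:
        scale = clean.std()
        corrupted[:, cols] = rng.normal(0.0, scale, size=(n, corrupt_cols))
    return clean, corrupted, cols


def make_dag_collection(
    n_diseases: int, depth: int = 3, branching: int = 2, seed: int = 0
) -> DiseaseDAGCollection:
    """Random forest-of-DAGs over the diseases themselves.

    Diseases are assigned levels 0..depth-1 (level 0 = roots); each disease at
    level l > 0 draws 1..branching parents from level l-1, so edges always
    point from deeper to shallower levels and every graph is acyclic by
    construction.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    diseases = [f"dis-{i:04d}" for i in range(n_diseases)]
    levels = rng.integers(0, depth, size=n_diseases)
    # guarantee at least one root
    levels[rng.integers(0, n_diseases)] = 0
    by_level: dict[int, list[int]] = {}
    for i, lv in enumerate(levels):
        by_level.setdefault(int(lv), []).append(i)
    # collapse empty levels so every non-root level has a parent pool
    parents_edges: dict[int, list[int]] = {i: [] for i in range(n_diseases)}
    occupied = sorted(by_level)
    for rank_idx, lv in enumerate(occupied[1:], start=1):
        pool = by_level[occupied[rank_idx - 1]]
        for i in by_level[lv]:
            n_par = int(rng.integers(1, branching + 1))
            chosen = rng.choice(pool, size=min(n_par, len(pool)), replace=False)
            parents_edges[i] = sorted(int(c) for c in chosen)

    direct = {diseases[i]: [diseases[p] for p in parents_edges[i]] for i in range(n_diseases)}
    ancestors: dict[str, frozenset[str]] = {}

    def closure(d: str) -> frozenset[str]:
        if d in ancestors:
            return ancestors[d]
        acc = {d}
        for p in direct[d]:
            acc |= closure(p)
        ancestors[d] = frozenset(acc)
        return ancestors[d]

    for d in diseases:
        closure(d)
    all_edges = {
        (child, parent) for child, ps in direct.items() for parent in ps
    }
    parent_edges = {
        d: frozenset(
            (c, p) for (c, p) in all_edges if c in ancestors[d] and p in ancestors[d]
        )
        for d in diseases
    }
    return DiseaseDAGCollection(diseases, ancestors, parent_edges)
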