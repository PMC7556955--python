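"""Disease semantic similarity, miRNA functional similarity, and GIP kernels.

Disease similarity combines two DAG-based models over the MeSH-style
ancestor graphs: model 1 assigns each ancestor a geometrically decaying
contribution (factor ``delta`` per layer towards the root), model 2 weighs an
ancestor by the negative log of its prevalence across all disease DAGs in the
collection; the two similarity matrices are averaged entrywise.

miRNA functional similarity (MISIM) scores two miRNAs by the average
best-match semantic similarity between their associated disease groups.

The Gaussian interaction profile (GIP) kernel measures how alike two
association profiles are, with the bandwidth normalised by the mean squared
profile norm so the kernel is insensitive to overall network density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._types import AssociationMatrix, DiseaseDAGCollection, SimilarityMatrix

__all__ = [
    "SemanticParams",
    "GipParams",
    "contribution_d1",
    "semantic_value_dv1",
    "similarity_ds1",
    "contribution_d2",
    "similarity_ds2",
    "disease_semantic_similarity",
    "misim",
    "associations_to_groups",
    "gip_kernel",
]


@dataclass(frozen=True)
class SemanticParams:
    """Parameters of the DAG semantic-similarity models.

    delta: semantic contribution factor in (0, 1); each layer away from the
        disease multiplies the contribution by delta. Default 0.5.
    log_base: base of the logarithm in the prevalence model. The choice
        rescales numerator and denominator jointly, leaving the similarity
        unchanged; natural log by default.
    """

    delta: float = 0.5
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise ValueError("log_base must be positive and != 1")


@dataclass(frozen=True)
class GipParams:
    """GIP kernel bandwidth multipliers (delta_m for miRNAs, delta_d for diseases)."""

    delta_m: float = 1.0
    delta_d: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_m <= 0 or self.delta_d <= 0:
            raise ValueError("bandwidth parameters must be positive")


def _require_disease(dags: DiseaseDAGCollection, disease: str) -> None:
    if disease not in dags:
        raise ValueError(f"disease {disease!r} not in collection")


def contribution_d1(
    dags: DiseaseDAGCollection,
    disease_A: str,
    params: SemanticParams = SemanticParams(),
) -> dict[str, float]:
    """Layer-decay contribution of every node of T(A) to disease A.

    The disease itself contributes 1; an ancestor t contributes
    ``delta * max(contribution of t's children within DAG(A))``, i.e. delta to
    the power of the shortest hop count from A to t along parent edges.
    """
    _require_disease(dags, disease_A)
    t_set = dags.ancestors[disease_A]
    edges = dags.parent_edges.get(disease_A, frozenset())
    children: dict[str, list[str]] = {t: [] for t in t_set}
    for child, parent in edges:
        children[parent].append(child)

    contrib: dict[str, float] = {}

    def value(t: str) -> float:
        if t in contrib:
            return contrib[t]
        if t == disease_A:
            contrib[t] = 1.0
        else:
            # acyclic, so the recursion terminates; nodes of T(A) are all
            # ancestors of A, hence have at least one child within T(A)
            contrib[t] = params.delta * max(value(c) for c in children[t])
        return contrib[t]

    for t in t_set:
        value(t)
    return contrib


def semantic_value_dv1(
    dags: DiseaseDAGCollection,
    disease_A: str,
    params: SemanticParams = SemanticParams(),
) -> float:
    """Semantic value DV1(A): sum of layer-decay contributions over T(A)."""
    return float(sum(contribution_d1(dags, disease_A, params).values()))


def similarity_ds1(
    dags: DiseaseDAGCollection,
    disease_A: str,
    disease_B: str,
    params: SemanticParams = SemanticParams(),
) -> float:
    """Layer-decay semantic similarity DS1(A, B) in [0, 1]."""
    ca = contribution_d1(dags, disease_A, params)
    cb = contribution_d1(dags, disease_B, params)
    shared = set(ca) & set(cb)
    num = sum(ca[t] + cb[t] for t in shared)
    den = sum(ca.values()) + sum(cb.values())
    return float(num / den)


def _dag_counts(dags: DiseaseDAGCollection) -> dict[str, int]:
    counts: dict[str, int] = {}
    for d in dags.diseases:
        for t in dags.ancestors[d]:
            counts[t] = counts.get(t, 0) + 1
    return counts


def contribution_d2(
    dags: DiseaseDAGCollection,
    node_t: str,
    params: SemanticParams = SemanticParams(),
) -> float:
    """Prevalence-based contribution: -log(fraction of DAGs containing t).

    Rare ancestors carry more information; a node present in every DAG
    contributes 0. Independent of which disease's DAG is being scored.
    """
    counts = _dag_counts(dags)
    if node_t not in counts:
        raise ValueError(f"node {node_t!r} appears in no disease DAG")
    frac = counts[node_t] / len(dags.diseases)
    return float(-math.log(frac, params.log_base))


def similarity_ds2(
    dags: DiseaseDAGCollection,
    disease_A: str,
    disease_B: str,
    params: SemanticParams = SemanticParams(),
) -> float:
    """Prevalence-weighted semantic similarity DS2(A, B).

    Defined as 0 when both semantic values vanish (every ancestor shared by
    all DAGs): the limit of vanishing information.
    """
    _require_disease(dags, disease_A)
    _require_disease(dags, disease_B)
    counts = _dag_counts(dags)
    n = len(dags.diseases)

    def d2(t: str) -> float:
        return -math.log(counts[t] / n, params.log_base)

    ta = dags.ancestors[disease_A]
    tb = dags.ancestors[disease_B]
    den = sum(d2(t) for t in ta) + sum(d2(t) for t in tb)
    if den == 0.0:
        import warnings

        warnings.warn(
            f"DS2({disease_A!r}, {disease_B!r}) undefined (zero semantic values); "
            "returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    num = sum(2.0 * d2(t) for t in ta & tb)
    return float(num / den)


def disease_semantic_similarity(
    dags: DiseaseDAGCollection,
    params: SemanticParams = SemanticParams(),
) -> SimilarityMatrix:
    """Combined disease semantic similarity: DS = (DS1 + DS2) / 2.

    The diagonal is forced to exactly 1 (DS1(A,A) is identically 1; DS2(A,A)
    is 1 whenever A's semantic value is positive).
    """
    diseases = dags.diseases
    n = len(diseases)
    contribs1 = {d: contribution_d1(dags, d, params) for d in diseases}
    counts = _dag_counts(dags)

    def d2(t: str) -> float:
        return -math.log(counts[t] / n, params.log_base)

    dv2 = {d: sum(d2(t) for t in dags.ancestors[d]) for d in diseases}
    dv1 = {d: sum(contribs1[d].values()) for d in diseases}
    out = np.eye(n)
    for i, a in enumerate(diseases):
        for j in range(i + 1, n):
            b = diseases[j]
            shared = dags.ancestors[a] & dags.ancestors[b]
            ds1 = (
                sum(contribs1[a][t] + contribs1[b][t] for t in shared)
                / (dv1[a] + dv1[b])
            )
            den2 = dv2[a] + dv2[b]
            ds2 = sum(2.0 * d2(t) for t in shared) / den2 if den2 > 0 else 0.0
            out[i, j] = out[j, i] = (ds1 + ds2) / 2.0
    return SimilarityMatrix(np.clip(out, 0.0, 1.0), list(diseases), "DS")


def misim(
    ds: SimilarityMatrix,
    mirna_to_diseases: Mapping[str, Sequence[str]],
) -> SimilarityMatrix:
    """miRNA functional similarity from associated disease groups.

    For miRNAs M1 (diseases D1, size m) and M2 (diseases D2, size n):

        MISIM(M1, M2) = (sum_i max_j DS(d1i, d2j) + sum_j max_i DS(d2j, d1i))
                        / (m + n)

    Every referenced disease must be present in ``ds``; a miRNA with an empty
    disease group is rejected (the best-match maximum would be undefined).
    """
    idx = {d: i for i, d in enumerate(ds.ids)}
    mirnas = sorted(mirna_to_diseases)
    groups: dict[str, np.ndarray] = {}
    for m in mirnas:
        dis = list(mirna_to_diseases[m])
        if not dis:
            raise ValueError(f"miRNA {m!r} has an empty disease set")
        missing = [d for d in dis if d not in idx]
        if missing:
            raise ValueError(f"miRNA {m!r} references unknown diseases: {missing}")
        groups[m] = np.array([idx[d] for d in dis])
    n = len(mirnas)
    out = np.eye(n)
    S = ds.values
    for i in range(n):
        gi = groups[mirnas[i]]
        for j in range(i + 1, n):
            gj = groups[mirnas[j]]
            block = S[np.ix_(gi, gj)]
            val = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(gi) + len(gj)
            )
            out[i, j] = out[j, i] = val
    return SimilarityMatrix(np.clip(out, 0.0, 1.0), mirnas, "MF")


def associations_to_groups(md: AssociationMatrix) -> dict[str, list[str]]:
    """miRNA -> associated-disease-group map from an association matrix.

    Convenience bridge into :func:`misim`; miRNAs without any association
    are omitted (MISIM requires a non-empty group).
    """
    out: dict[str, list[str]] = {}
    for i, m in enumerate(md.mirna_ids):
        group = [md.disease_ids[j] for j in np.flatnonzero(md.values[i])]
        if group:
            out[m] = group
    return out


def gip_kernel(
    md: AssociationMatrix,
    axis: str,
    params: GipParams = GipParams(),
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over association profiles.

    ``axis='mirna'`` uses rows of MD as profiles (role GM), ``axis='disease'``
    columns (role GD). The bandwidth is gamma = delta / mean(||profile||^2),
    so duplicating the association pattern of every entity leaves the kernel
    unchanged.
    """
    if axis == "mirna":
        profiles = md.values.astype(float)
        ids, role, delta = md.mirna_ids, "GM", params.delta_m
    elif axis == "disease":
        profiles = md.values.T.astype(float)
        ids, role, delta = md.disease_ids, "GD", params.delta_d
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    gamma = delta / mean_sq
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i.p_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    kernel = np.exp(-gamma * d2)
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix((kernel + kernel.T) / 2.0, list(ids), role)
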