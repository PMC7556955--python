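"""Core labelled-matrix containers shared across the pipeline.

All matrices follow one orientation convention: rows are miRNAs, columns are
diseases, matching the MD(m_i, d_j) indexing of the association matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SIMILARITY_ROLES = frozenset(
    {"MF", "DS", "GM", "GD", "CM", "CD", "IMS", "IDS"}
)


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} label: {dup!r}")
    return labels


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix MD."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        nm, nd = self.values.shape
        if nm != len(self.mirna_ids) or nd != len(self.disease_ids):
            raise ValueError("label count does not match matrix shape")
        if nm < 2 or nd < 2:
            raise ValueError("need at least 2 miRNAs and 2 diseases")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at row {self.mirna_ids[bad[0]]!r}, "
                f"column {self.disease_ids[bad[1]]!r}: {self.values[tuple(bad)]}"
            )
        if self.values.sum() == 0:
            raise ValueError("association matrix has no known associations")
        self.values = self.values.astype(np.int8)

    @property
    def nm(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )


@dataclass
class SimilarityMatrix:
    """Square labelled similarity matrix with a pipeline role tag.

    Roles: MF (miRNA functional), DS (disease semantic), GM/GD (GIP kernels),
    CM/CD (completed), IMS/IDS (integrated).
    """

    values: np.ndarray
    ids: list[str]
    role: str = "MF"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_unique(self.ids, "similarity")
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix must be {n}x{n}, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix has non-finite entries")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"similarity matrix asymmetric (max |S-S^T| = {asym:g})")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PredictionMatrix:
    """Real-valued association scores with the source labels."""

    scores: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("score shape does not match labels")
        if not np.isfinite(self.scores).all():
            raise ValueError("prediction matrix has non-finite entries")


@dataclass
class DiseaseDAGCollection:
    """Per-disease ancestor DAGs: DAG(D) = (D, T(D), E(D)).

    ``ancestors[D]`` is T(D), the node D plus all its transitive ancestors;
    ``parent_edges[D]`` is E(D), the (child, parent) edges among T(D).
    """

    diseases: list[str]
    ancestors: Mapping[str, frozenset[str]]
    parent_edges: Mapping[str, frozenset[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diseases = _check_unique(self.diseases, "disease")
        for d in self.diseases:
            if d not in self.ancestors:
                raise ValueError(f"no ancestor set for disease {d!r}")
            if d not in self.ancestors[d]:
                raise ValueError(f"T({d}) must contain {d} itself")
            for child, parent in self.parent_edges.get(d, ()):  # type: ignore[union-attr]
                if child not in self.ancestors[d] or parent not in self.ancestors[d]:
                    raise ValueError(f"edge ({child}, {parent}) leaves T({d})")

    def __contains__(self, disease: str) -> bool:
        return disease in set(self.diseases)
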