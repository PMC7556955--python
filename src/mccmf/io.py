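"""Readers and writers for the pipeline's plain-text formats.

Supported formats: association edge lists (``mirna<TAB>disease``), dense
labelled CSV/TSV matrices (first row and first column carry labels, delimiter
autodetected from the ``.csv``/``.tsv`` extension), disease-ontology edge
lists (``child<TAB>parent``), and ranked prediction tables.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._types import (
    AssociationMatrix,
    DiseaseDAGCollection,
    PredictionMatrix,
    SimilarityMatrix,
)

__all__ = [
    "read_association",
    "write_association",
    "read_similarity",
    "write_similarity",
    "read_dag_collection",
    "write_ranked_predictions",
    "ranked_predictions",
]


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_header_unique(path: Path, sep: str) -> None:
    # pandas mangles duplicate header labels (d, d.1, ...); catch them first
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValueError(f"{path}: duplicate label {label!r} in header")
        seen.add(label)


def read_association(path: str | os.PathLike, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary miRNA-disease association matrix.

    ``format='edge_list'``: two tab-separated columns (miRNA, disease), one
    association per line; duplicates collapse; labels are sorted
    lexicographically for a deterministic order. ``format='dense'``: labelled
    matrix keeping file order; every entry must be 0 or 1.
    """
    path = Path(path)
    if format == "edge_list":
        pairs: set[tuple[str, str]] = set()
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                pairs.add((fields[0].strip(), fields[1].strip()))
        if not pairs:
            raise ValueError(f"{path}: empty edge list")
        mirnas = sorted({m for m, _ in pairs})
        diseases = sorted({d for _, d in pairs})
        mi = {m: i for i, m in enumerate(mirnas)}
        di = {d: j for j, d in enumerate(diseases)}
        values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
        for m, d in pairs:
            values[mi[m], di[d]] = 1
        return AssociationMatrix(values, mirnas, diseases)
    if format == "dense":
        _check_header_unique(path, _sep_for(path))
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        values = df.to_numpy()
        bad = np.argwhere(~np.isin(values, (0, 1)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: non-binary value {values[i, j]!r} at "
                f"row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        return AssociationMatrix(values.astype(np.int8), list(df.index), list(df.columns))
    raise ValueError(f"unknown format {format!r}; expected 'edge_list' or 'dense'")


def write_association(md: AssociationMatrix, path: str | os.PathLike) -> None:
    """Write an association matrix as a dense labelled table."""
    pd.DataFrame(md.values, index=md.mirna_ids, columns=md.disease_ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_similarity(path: str | os.PathLike, role: str = "MF") -> SimilarityMatrix:
    """Read a dense labelled square similarity matrix.

    Asymmetry up to 1e-6 is repaired by averaging with the transpose; larger
    asymmetry is rejected, reporting the worst cell.
    """
    path = Path(path)
    _check_header_unique(path, _sep_for(path))
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square, got {values.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels differ from column labels")
    asym = np.abs(values - values.T)
    if asym.size and asym.max() > 1e-6:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: asymmetry {asym[i, j]:g} at ({df.index[i]!r}, {df.columns[j]!r}) "
            "exceeds 1e-6"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, list(df.index), role)


def write_similarity(sim: SimilarityMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_dag_collection(
    edges_path: str | os.PathLike, disease_list_path: str | os.PathLike
) -> DiseaseDAGCollection:
    """Build per-disease ancestor DAGs from a global ontology edge list.

    ``edges_path`` holds ``child<TAB>parent`` lines; ``disease_list_path``
    names the diseases of interest, one per line. T(D) is D plus its
    transitive ancestors; E(D) is every ontology edge among T(D).
    """
    graph = nx.DiGraph()  # edges point child -> parent
    with Path(edges_path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{edges_path}:{lineno}: expected 'child<TAB>parent'")
            graph.add_edge(fields[0].strip(), fields[1].strip())
    diseases = [
        line.strip() for line in Path(disease_list_path).read_text().splitlines() if line.strip()
    ]
    ancestors: dict[str, frozenset[str]] = {}
    parent_edges: dict[str, frozenset[tuple[str, str]]] = {}
    for d in diseases:
        if graph.has_node(d):
            # reachable-along-parent-edges = ancestors
            t_set = {d} | nx.descendants(graph, d)
        else:
            t_set = {d}
        sub = graph.subgraph(t_set)
        if sub.number_of_edges() and not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            raise ValueError(
                f"cycle in ontology reachable from {d!r}: involves node {cycle[0][0]!r}"
            )
        ancestors[d] = frozenset(t_set)
        parent_edges[d] = frozenset(sub.edges())
    return DiseaseDAGCollection(diseases, ancestors, parent_edges)


def ranked_predictions(
    pred: PredictionMatrix,
    md: AssociationMatrix,
    disease_id: str,
    top_n: int,
) -> pd.DataFrame:
    """Rank miRNAs for one disease; ties broken by miRNA label.

    Rows already supported by the association matrix are flagged ``known``,
    the rest ``novel``.
    """
    if disease_id not in md.disease_ids:
        raise ValueError(
            f"unknown disease {disease_id!r}; valid ids: {', '.join(md.disease_ids)}"
        )
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    j = md.disease_ids.index(disease_id)
    order = sorted(
        range(md.nm), key=lambda i: (-pred.scores[i, j], md.mirna_ids[i])
    )[: min(top_n, md.nm)]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "mirna": [md.mirna_ids[i] for i in order],
            "score": [pred.scores[i, j] for i in order],
            "status": ["known" if md.values[i, j] else "novel" for i in order],
        }
    )


def write_ranked_predictions(
    pred: PredictionMatrix,
    md: AssociationMatrix,
    disease_id: str,
    top_n: int,
    path: str | os.PathLike,
) -> pd.DataFrame:
    """Write the ranked table for one disease as TSV and return it."""
    table = ranked_predictions(pred, md, disease_id, top_n)
    table.to_csv(path, sep="\t", index=False)
    return table
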