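import numpy as np
import pytest

from mccmf import (
    AssociationMatrix,
    DiseaseDAGCollection,
    SimilarityMatrix,
    SyntheticConfig,
    make_problem,
)


@pytest.fixture(scope="session")
def default_problem():
    """The planted 150x100 rank-5 problem used by the integration tests."""
    return make_problem(SyntheticConfig())


@pytest.fixture(scope="session")
def small_problem():
    return make_problem(SyntheticConfig(nm=40, nd=30, density=0.15, seed=3))


@pytest.fixture
def shared_parent_dags():
    """A and B share parent p; C isolated. DS1(A,B) = 1/3 at delta = 0.5."""
    return DiseaseDAGCollection(
        diseases=["A", "B", "C"],
        ancestors={
            "A": frozenset({"A", "p"}),
            "B": frozenset({"B", "p"}),
            "C": frozenset({"C"}),
        },
        parent_edges={
            "A": frozenset({("A", "p")}),
            "B": frozenset({("B", "p")}),
            "C": frozenset(),
        },
    )


@pytest.fixture
def chain_dags():
    """A -> p -> g ancestor chain (plus an unrelated root disease)."""
    return DiseaseDAGCollection(
        diseases=["A", "Z"],
        ancestors={"A": frozenset({"A", "p", "g"}), "Z": frozenset({"Z"})},
        parent_edges={
            "A": frozenset({("A", "p"), ("p", "g")}),
            "Z": frozenset(),
        },
    )


def random_similarity(n, rng, role="MF"):
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, [f"x{i:03d}" for i in range(n)], role)


@pytest.fixture
def tiny_md():
    values = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8)
    return AssociationMatrix(values, ["m1", "m2", "m3", "m4"], ["d1", "d2", "d3"])
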