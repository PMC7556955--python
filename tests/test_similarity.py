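import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mccmf import (
    AssociationMatrix,
    DiseaseDAGCollection,
    GipParams,
    SemanticParams,
    SimilarityMatrix,
    disease_semantic_similarity,
    gip_kernel,
    make_dag_collection,
    misim,
)
from mccmf.similarity import (
    contribution_d1,
    contribution_d2,
    semantic_value_dv1,
    similarity_ds1,
    similarity_ds2,
)


def brute_force_d1(dags, disease, delta):
    """Independent oracle: max of delta^len over all directed paths t -> A."""
    edges = dags.parent_edges[disease]
    children = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)

    out = {}
    for t in dags.ancestors[disease]:
        best = None
        stack = [(t, 0)]
        while stack:
            node, length = stack.pop()
            if node == disease:
                val = delta**length
                best = val if best is None else max(best, val)
                continue
            for c in children.get(node, []):
                stack.append((c, length + 1))
        out[t] = best
    return out


class TestLayerDecayModel:
    def test_self_contribution_is_one(self, chain_dags):
        assert contribution_d1(chain_dags, "A")["A"] == 1.0

    def test_chain_values(self, chain_dags):
        c = contribution_d1(chain_dags, "A", SemanticParams(delta=0.5))
        assert c == {"A": 1.0, "p": 0.5, "g": 0.25}

    def test_diamond_takes_max_over_paths(self):
        dags = DiseaseDAGCollection(
            diseases=["A"],
            ancestors={"A": frozenset({"A", "p1", "p2", "g"})},
            parent_edges={
                "A": frozenset(
                    {("A", "p1"), ("A", "p2"), ("p1", "g"), ("p2", "g")}
                )
            },
        )
        c = contribution_d1(dags, "A", SemanticParams(delta=0.5))
        assert c["g"] == pytest.approx(0.25)

    def test_missing_disease_rejected(self, chain_dags):
        with pytest.raises(ValueError, match="not in collection"):
            contribution_d1(chain_dags, "nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_path_enumeration_oracle(self, seed):
        dags = make_dag_collection(8, depth=4, branching=3, seed=seed)
        params = SemanticParams(delta=0.4)
        for d in dags.diseases:
            oracle = brute_force_d1(dags, d, 0.4)
            got = contribution_d1(dags, d, params)
            assert got.keys() == oracle.keys()
            for t in got:
                assert got[t] == pytest.approx(oracle[t], abs=1e-12)

    def test_dv1_values(self, chain_dags, shared_parent_dags):
        assert semantic_value_dv1(shared_parent_dags, "C") == 1.0
        assert semantic_value_dv1(shared_parent_dags, "A") == pytest.approx(1.5)
        assert semantic_value_dv1(chain_dags, "A") == pytest.approx(1.75)

    def test_ds1_identity_and_disjoint(self, shared_parent_dags):
        assert similarity_ds1(shared_parent_dags, "A", "A") == pytest.approx(1.0)
        assert similarity_ds1(shared_parent_dags, "A", "C") == 0.0

    def test_ds1_shared_parent_closed_form(self, shared_parent_dags):
        # (0.5 + 0.5) / (1.5 + 1.5) = 1/3
        v = similarity_ds1(shared_parent_dags, "A", "B", SemanticParams(delta=0.5))
        assert v == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert v == similarity_ds1(shared_parent_dags, "B", "A")


class TestPrevalenceModel:
    def test_ubiquitous_node_contributes_zero(self, shared_parent_dags):
        dags = DiseaseDAGCollection(
            diseases=["A", "B"],
            ancestors={"A": frozenset({"A", "r"}), "B": frozenset({"B", "r"})},
            parent_edges={
                "A": frozenset({("A", "r")}),
                "B": frozenset({("B", "r")}),
            },
        )
        assert contribution_d2(dags, "r") == 0.0

    def test_half_prevalence_is_log2(self):
        dags = DiseaseDAGCollection(
            diseases=["A", "B"],
            ancestors={"A": frozenset({"A", "p"}), "B": frozenset({"B"})},
            parent_edges={"A": frozenset({("A", "p")}), "B": frozenset()},
        )
        assert contribution_d2(dags, "p") == pytest.approx(math.log(2), abs=1e-12)

    def test_absent_node_rejected(self, shared_parent_dags):
        with pytest.raises(ValueError, match="no disease DAG"):
            contribution_d2(shared_parent_dags, "zzz")

    def test_ds2_hand_value(self, shared_parent_dags):
        # collection {A->p, B->p, C}: D2(p) = log(3/2), D2(A) = D2(B) = log 3
        expected = (2 * math.log(1.5)) / (2 * (math.log(3) + math.log(1.5)))
        got = similarity_ds2(shared_parent_dags, "A", "B")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_ds2_identical_t_sets(self):
        dags = DiseaseDAGCollection(
            diseases=["A", "B", "C"],
            ancestors={
                "A": frozenset({"A", "p"}),
                "B": frozenset({"B", "p"}),
                "C": frozenset({"C", "p"}),
            },
            parent_edges={d: frozenset({(d, "p")}) for d in "ABC"},
        )
        # shared-prevalence node p contributes log(3/3)=0 but A/B contribute
        assert similarity_ds2(dags, "A", "A") == pytest.approx(1.0)

    def test_ds2_zero_denominator_warns(self):
        dags = DiseaseDAGCollection(
            diseases=["A"],
            ancestors={"A": frozenset({"A"})},
            parent_edges={"A": frozenset()},
        )
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert similarity_ds2(dags, "A", "A") == 0.0


class TestCombinedSemanticSimilarity:
    def test_diagonal_is_one(self, shared_parent_dags):
        ds = disease_semantic_similarity(shared_parent_dags)
        np.testing.assert_allclose(np.diag(ds.values), 1.0)

    def test_entry_matches_per_pair_average(self, shared_parent_dags):
        ds = disease_semantic_similarity(shared_parent_dags)
        i, j = 0, 1  # A, B
        expected = (
            similarity_ds1(shared_parent_dags, "A", "B")
            + similarity_ds2(shared_parent_dags, "A", "B")
        ) / 2.0
        assert ds.values[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_output_is_valid_similarity(self, seed):
        dags = make_dag_collection(12, depth=3, branching=2, seed=seed)
        ds = disease_semantic_similarity(dags)
        assert np.abs(ds.values - ds.values.T).max() < 1e-10
        assert ds.values.min() >= 0.0 and ds.values.max() <= 1.0
        np.testing.assert_allclose(np.diag(ds.values), 1.0)


class TestMisim:
    @pytest.fixture
    def ds3(self):
        vals = np.array(
            [[1.0, 0.4, 0.0], [0.4, 1.0, 0.2], [0.0, 0.2, 1.0]]
        )
        return SimilarityMatrix(vals, ["d1", "d2", "d3"], "DS")

    def test_identical_groups_give_one(self, ds3):
        mf = misim(ds3, {"m1": ["d1", "d2"], "m2": ["d1", "d2"]})
        assert mf.values[0, 1] == pytest.approx(1.0)

    def test_single_disease_hand_value(self, ds3):
        mf = misim(ds3, {"m1": ["d1"], "m2": ["d2"]})
        assert mf.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_disjoint_zero(self, ds3):
        mf = misim(ds3, {"m1": ["d1"], "m2": ["d3"]})
        assert mf.values[0, 1] == 0.0

    def test_empty_group_rejected(self, ds3):
        with pytest.raises(ValueError, match="empty disease set"):
            misim(ds3, {"m1": [], "m2": ["d1"]})

    def test_monotone_in_cross_similarity(self, ds3):
        lo = misim(ds3, {"m1": ["d1"], "m2": ["d3"]}).values[0, 1]
        raised = ds3.values.copy()
        raised[0, 2] = raised[2, 0] = 0.3
        hi = misim(
            SimilarityMatrix(raised, ds3.ids, "DS"), {"m1": ["d1"], "m2": ["d3"]}
        ).values[0, 1]
        assert hi >= lo


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        md = AssociationMatrix(
            np.array([[1, 0], [1, 0], [0, 1]]), ["a", "b", "c"], ["x", "y"]
        )
        gm = gip_kernel(md, "mirna")
        assert gm.values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        sub = AssociationMatrix(np.array([[1, 0], [0, 0]]), ["a", "b"], ["x", "y"])
        gm = gip_kernel(sub, "mirna", GipParams(delta_m=1.0))
        # gamma = 1 / ((1 + 0)/2) = 2; ||p1 - p2||^2 = 1
        assert gm.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_duplication_invariance(self, tiny_md):
        gm = gip_kernel(tiny_md, "mirna")
        doubled = AssociationMatrix(
            np.vstack([tiny_md.values, tiny_md.values]),
            tiny_md.mirna_ids + [m + "_copy" for m in tiny_md.mirna_ids],
            tiny_md.disease_ids,
        )
        gm2 = gip_kernel(doubled, "mirna")
        np.testing.assert_allclose(
            gm2.values[: tiny_md.nm, : tiny_md.nm], gm.values, atol=1e-12
        )

    def test_strictly_decreasing_in_profile_distance(self):
        md = AssociationMatrix(
            np.array(
                [[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0], [0, 1, 1, 1]]
            ),
            list("abcd"),
            list("wxyz"),
        )
        gm = gip_kernel(md, "mirna").values
        prof = md.values.astype(float)
        d = ((prof[:, None] - prof[None]) ** 2).sum(-1)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if d[i, j] < d[i, k]:
                        assert gm[i, j] > gm[i, k]

    def test_disease_axis_uses_columns(self, tiny_md):
        gd = gip_kernel(tiny_md, "disease")
        assert gd.ids == tiny_md.disease_ids
        assert gd.role == "GD"

    def test_invalid_axis_and_params_rejected(self, tiny_md):
        with pytest.raises(ValueError, match="axis"):
            gip_kernel(tiny_md, "gene")
        with pytest.raises(ValueError, match="positive"):
            GipParams(delta_m=0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_semantic_similarity_invariants_random_dags(seed):
    dags = make_dag_collection(6, depth=3, branching=2, seed=seed)
    ds = disease_semantic_similarity(dags)
    assert np.abs(ds.values - ds.values.T).max() < 1e-10
    assert (ds.values >= 0).all() and (ds.values <= 1).all()
    np.testing.assert_allclose(np.diag(ds.values), 1.0)
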