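import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocumir.clustering import (
    average_linkage,
    distance_matrix,
    supervised_cluster,
    uncentered_distance,
)
from ocumir.normalization import detectability_filter, median_normalize

from oracles import naive_upgma


class TestUncenteredDistance:
    def test_self_similarity_zero(self):
        x = np.array([1.0, 2.0, -3.0, 4.0])
        assert uncentered_distance(x, x) == pytest.approx(0.0)

    def test_anticorrelation_hits_two(self):
        x = np.array([1.0, 2.0, -3.0, 4.0])
        assert uncentered_distance(x, -x) == pytest.approx(2.0)

    def test_orthogonal_vectors_distance_one(self):
        assert uncentered_distance([1.0, 0.0, 5.0], [0.0, 1.0, 0.0],
                                   min_overlap=2) == pytest.approx(1.0)

    def test_low_overlap_falls_back_to_one(self):
        x = np.array([1.0, np.nan, np.nan, 2.0])
        y = np.array([1.0, 1.0, 1.0, np.nan])
        assert uncentered_distance(x, y, min_overlap=3) == 1.0

    def test_all_zero_overlap_falls_back_to_one(self):
        assert uncentered_distance([0.0, 0.0, 0.0], [1.0, 2.0, 3.0],
                                   min_overlap=3) == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, data):
        n = data.draw(st.integers(3, 10))
        finite = st.floats(-5, 5, allow_nan=False)
        x = np.array(data.draw(st.lists(finite, min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(finite, min_size=n, max_size=n)))
        d_xy = uncentered_distance(x, y)
        assert d_xy == uncentered_distance(y, x)
        assert 0.0 <= d_xy <= 2.0


class TestAverageLinkage:
    def test_hand_worked_three_items(self):
        dist = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        result = average_linkage(dist)
        assert result.merges[0] == ("A", "B", pytest.approx(0.1))
        a, b, h = result.merges[1]
        assert {a, b} == {"NODE1", "C"} and h == pytest.approx(0.9)

    def test_duplicate_items_merge_first_at_zero(self):
        dist = pd.DataFrame(
            [[0.0, 0.0, 0.7], [0.0, 0.0, 0.7], [0.7, 0.7, 0.0]],
            index=list("XYZ"), columns=list("XYZ"),
        )
        result = average_linkage(dist)
        assert result.merges[0] == ("X", "Y", 0.0)

    def test_single_item_rejected(self):
        dist = pd.DataFrame([[0.0]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            average_linkage(dist)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_matches_naive_upgma_oracle(self, n):
        rng = np.random.default_rng(n)
        for rep in range(15):
            m = rng.uniform(0.0, 2.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            ids = [f"i{k}" for k in range(n)]
            dist = pd.DataFrame(m, index=ids, columns=ids)
            result = average_linkage(dist)
            oracle_merges, oracle_order = naive_upgma(ids, m.tolist())
            assert result.leaf_order == oracle_order
            assert len(result.merges) == n - 1
            for (a, b, h), (oa, ob, oh) in zip(result.merges, oracle_merges):
                assert (a, b) == (oa, ob)
                assert h == pytest.approx(oh, rel=1e-12)

    def test_leaf_order_is_dendrogram_consistent(self):
        """Each internal node's leaves occupy a contiguous block of the
        leaf order."""
        rng = np.random.default_rng(99)
        n = 8
        m = rng.uniform(0, 2, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{k}" for k in range(n)]
        result = average_linkage(pd.DataFrame(m, index=ids, columns=ids))
        members = {it: [it] for it in ids}
        pos = {it: i for i, it in enumerate(result.leaf_order)}
        for j, (a, b, _) in enumerate(result.merges, start=1):
            leaves = members[a] + members[b]
            members[f"NODE{j}"] = leaves
            positions = sorted(pos[leaf] for leaf in leaves)
            assert positions == list(range(positions[0], positions[0] + len(leaves)))


class TestSupervisedCluster:
    def test_strong_effects_separate_groups_at_root(self, small_cohort):
        """Clustering on the truly differential assays splits the dendrogram
        root into near-pure group branches."""
        ct, annot, truth = small_cohort
        expr = median_normalize(detectability_filter(ct))
        subset = [a for a in truth["assay_id"].unique() if a in expr.columns]
        result, purity = supervised_cluster(expr, annot, subset)
        assert (purity["purity"] >= 0.9).all()
        assert set(purity["majority_group"]) == {"control", "OSC"}

    def test_single_assay_subset_still_full_tree(self, small_cohort):
        ct, annot, _ = small_cohort
        expr = median_normalize(detectability_filter(ct))
        assay = expr.columns[expr.notna().all()][0]
        result, _ = supervised_cluster(expr, annot, [assay], min_overlap=1)
        assert len(result.merges) == len(expr) - 1

    def test_relabeling_samples_does_not_change_topology(self, small_cohort):
        ct, annot, truth = small_cohort
        expr = median_normalize(detectability_filter(ct))
        subset = [a for a in truth["assay_id"].unique() if a in expr.columns]
        result1, _ = supervised_cluster(expr, annot, subset)
        relabeled = annot.copy()
        relabeled["group"] = np.where(relabeled["group"] == "OSC", "g1", "g2")
        result2, _ = supervised_cluster(expr, relabeled, subset)
        assert result1.merges == result2.merges
        assert result1.leaf_order == result2.leaf_order

    def test_empty_or_unknown_subset_rejected(self, small_cohort):
        ct, annot, _ = small_cohort
        expr = median_normalize(detectability_filter(ct))
        with pytest.raises(ValueError):
            supervised_cluster(expr, annot, [])
        with pytest.raises(ValueError, match="not in expression"):
            supervised_cluster(expr, annot, ["no-such-assay"])


def test_distance_matrix_is_valid_metric_input(small_cohort):
    ct, _, _ = small_cohort
    expr = median_normalize(detectability_filter(ct)).iloc[:10]
    dist = distance_matrix(expr)
    v = dist.to_numpy()
    assert np.allclose(v, v.T)
    assert np.allclose(np.diag(v), 0.0)
    assert v.min() >= 0.0 and v.max() <= 2.0
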