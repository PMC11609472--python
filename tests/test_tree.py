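"""Single-tree growth: impurity, split search, latent scores, routing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clifitree.tree import (
    DecisionTree,
    DegenerateNodeError,
    LabeledDataset,
    TreeParams,
    apply_tree,
    find_best_split,
    gini_impurity,
    grow_tree,
    lava_latent_scores,
)
from clifitree.network import identity_neighbourhoods


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [((5, 0), 0.0), ((2, 2), 0.5), ((3, 1), 0.375), ((1, 1, 1), 2 / 3)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_all_zero_counts_raise(self):
        with pytest.raises(DegenerateNodeError):
            gini_impurity((0, 0))

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    @settings(max_examples=50, derandomize=True)
    def test_bounds(self, counts):
        g = gini_impurity(counts)
        K = len(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / K + 1e-12


def brute_force_best_split(x, y, mode):
    """Independent oracle: enumerate every midpoint threshold."""
    x = np.asarray(x, float)
    vals = np.unique(x)
    best = None
    n = len(x)
    for lo, hi in zip(vals[:-1], vals[1:]):
        t = (lo + hi) / 2
        left, right = y[x <= t], y[x > t]
        if mode == "classification":
            def imp(lab):
                _, c = np.unique(lab, return_counts=True)
                return 1 - ((c / c.sum()) ** 2).sum()
            gain = imp(y) - (len(left) * imp(left) + len(right) * imp(right)) / n
        else:
            def sse(v):
                return ((v - v.mean()) ** 2).sum()
            gain = (sse(y) - sse(left) - sse(right)) / n
        if best is None or gain > best[1] + 1e-12:
            best = (t, gain)
    return best


class TestFindBestSplit:
    def test_perfectly_separable(self):
        t, g = find_best_split(np.array([1, 2, 3, 4.0]), np.array(list("aabb")))
        assert t == pytest.approx(2.5)
        assert g == pytest.approx(0.5)

    def test_constant_column_sentinel(self):
        assert find_best_split(np.array([1.0, 1, 1]), np.array(list("aba"))) is None

    def test_matches_bruteforce_example(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array(list("aabab"))
        got = find_best_split(x, y)
        want = brute_force_best_split(x, y, "classification")
        assert got == pytest.approx(want)

    @given(st.data())
    @settings(max_examples=40, derandomize=True)
    def test_matches_bruteforce_random(self, data):
        n = data.draw(st.integers(4, 30))
        x = np.array(data.draw(st.lists(st.integers(0, 9), min_size=n, max_size=n)), float)
        mode = data.draw(st.sampled_from(["classification", "regression"]))
        if mode == "classification":
            y = np.array(data.draw(st.lists(st.sampled_from("abc"), min_size=n, max_size=n)))
        else:
            y = np.array(
                data.draw(st.lists(st.integers(-5, 5), min_size=n, max_size=n)), float
            )
        got = find_best_split(x, y, mode)
        if len(np.unique(x)) < 2:
            assert got is None
            return
        want = brute_force_best_split(x, y, mode)
        if got is None:
            assert want[1] <= 1e-9
        else:
            assert got[1] == pytest.approx(want[1], abs=1e-9)
            assert got[1] >= 0


class TestLavaLatentScores:
    def test_single_feature_identity_after_centering(self):
        scores, loadings, center = lava_latent_scores(np.array([[1.0], [2], [3]]))
        assert loadings == pytest.approx([1.0])
        assert center == pytest.approx([2.0])
        assert scores == pytest.approx([-1, 0, 1])

    def test_duplicated_column_closed_form(self):
        X = np.array([[1.0, 1], [2, 2], [3, 3]])
        scores, loadings, _ = lava_latent_scores(X)
        assert loadings == pytest.approx([0.70711, 0.70711], abs=1e-5)
        assert scores == pytest.approx([-1.41421, 0, 1.41421], abs=1e-5)

    def test_matches_full_svd(self):
        X = np.array([[0.0, 0], [1, 2], [2, 1]])
        scores, loadings, center = lava_latent_scores(X)
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc)
        v = vt[0] if vt[0][np.argmax(np.abs(vt[0]))] > 0 else -vt[0]
        assert loadings == pytest.approx(v)
        assert scores == pytest.approx(Xc @ v)
        assert np.linalg.norm(loadings) == pytest.approx(1.0)

    def test_zero_variance_degrades_to_anchor(self):
        X = np.full((4, 3), 2.0)
        scores, loadings, _ = lava_latent_scores(X, anchor_position=1)
        assert loadings == pytest.approx([0, 1, 0])
        assert scores == pytest.approx([0, 0, 0, 0])


def assert_counts_consistent(tree):
    for node in tree.internal_nodes():
        s = node.split
        for c, n in s.class_counts_parent.items():
            assert s.class_counts_left.get(c, 0) + s.class_counts_right.get(c, 0) == n
    root = tree.nodes[0]
    if root.split is not None:
        assert root.split.class_counts_parent == tree.root_class_counts


class TestGrowTree:
    def test_separable_depth_one(self, separable_2class, all_features_params):
        tree = grow_tree(separable_2class, all_features_params)
        assert len(tree.internal_nodes()) == 1
        leaf_counts = sorted(
            tuple(l.class_counts.get(c, 0) for c in tree.class_list)
            for l in tree.leaves()
        )
        assert leaf_counts == [(0, 2), (2, 0)]
        assert_counts_consistent(tree)

    def test_pure_labels_single_leaf(self, all_features_params):
        ds = LabeledDataset(np.array([[1.0], [2], [3]]), np.array(["a"] * 3, dtype=object))
        tree = grow_tree(ds, all_features_params)
        assert tree.internal_nodes() == []
        assert len(tree.nodes) == 1

    def test_identity_neighbourhoods_equal_plain(self, toy_3class):
        params = TreeParams(max_features="sqrt", rng_seed=42)
        plain = grow_tree(toy_3class, params, rng=np.random.default_rng(42))
        lava = grow_tree(
            toy_3class,
            params,
            identity_neighbourhoods(toy_3class.n_features),
            rng=np.random.default_rng(42),
        )
        assert plain.to_dict() == lava.to_dict()

    def test_counts_consistent_on_random_data(self, toy_3class):
        tree = grow_tree(toy_3class, TreeParams(max_features="sqrt", rng_seed=3))
        assert_counts_consistent(tree)

    def test_serialization_roundtrip(self, toy_3class, all_features_params):
        tree = grow_tree(toy_3class, all_features_params)
        clone = DecisionTree.from_json(tree.to_json())
        assert clone.to_dict() == tree.to_dict()
        _, p1 = apply_tree(tree, toy_3class.X)
        _, p2 = apply_tree(clone, toy_3class.X)
        assert (p1 == p2).all()


class TestApplyTree:
    def test_training_leaf_membership_reproduced(self, toy_3class, all_features_params):
        tree = grow_tree(toy_3class, all_features_params)
        leaf_ids, _ = apply_tree(tree, toy_3class.X)
        for leaf in tree.leaves():
            routed = np.flatnonzero(leaf_ids == leaf.node_id)
            assert sorted(routed) == sorted(leaf.train_indices)

    def test_depth_one_routing(self, separable_2class, all_features_params):
        tree = grow_tree(separable_2class, all_features_params)
        _, preds = apply_tree(tree, np.array([[2.0], [3.0]]))
        assert list(preds) == ["a", "b"]

    def test_lava_node_projection_routing(self):
        d = {
            "mode": "classification",
            "class_list": ["l", "r"],
            "n_features": 2,
            "root_class_counts": [["l", 1], ["r", 1]],
            "nodes": [
                {"node_id": 0, "left": 1, "right": 2, "split": {
                    "feature_index": 0, "neighbourhood": [0, 1],
                    "loadings": [0.70711, 0.70711], "center": [2.0, 2.0],
                    "threshold": 0.0,
                    "class_counts_parent": [["l", 1], ["r", 1]],
                    "class_counts_left": [["l", 1], ["r", 0]],
                    "class_counts_right": [["l", 0], ["r", 1]],
                    "impurity_decrease": 0.5}},
                {"node_id": 1, "left": -1, "right": -1,
                 "leaf": {"class_counts": [["l", 1]], "value": None}},
                {"node_id": 2, "left": -1, "right": -1,
                 "leaf": {"class_counts": [["r", 1]], "value": None}},
            ],
        }
        tree = DecisionTree.from_dict(d)
        # projection 0.70711*(3-2) + 0.70711*(3-2) > 0 -> right
        _, preds = apply_tree(tree, np.array([[3.0, 3.0], [1.0, 1.0]]))
        assert list(preds) == ["r", "l"]

    def test_shape_mismatch_raises(self, separable_2class, all_features_params):
        tree = grow_tree(separable_2class, all_features_params)
        with pytest.raises(ValueError):
            apply_tree(tree, np.zeros((2, 3)))
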