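import numpy as np
import pytest

from clifitree.tree import LabeledDataset, TreeParams


@pytest.fixture
def separable_2class():
    """Four samples, one feature, perfectly separable at 2.5."""
    return LabeledDataset(
        np.array([[1.0], [2.0], [3.0], [4.0]]),
        np.array(["a", "a", "b", "b"], dtype=object),
    )


@pytest.fixture
def toy_3class():
    """Three well-separated Gaussian blobs over two features."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    X = np.vstack([rng.normal(c, 0.5, size=(15, 2)) for c in centers])
    y = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15, dtype=object)
    return LabeledDataset(X, y)


@pytest.fixture
def all_features_params():
    return TreeParams(mode="classification", max_features="all", rng_seed=0)


@pytest.fixture
def two_tree_toy():
    """Hand-built 2-tree ensemble: samples x=0 and x=1 share a leaf in
    exactly one of the two trees (a stump at 0.5 and a single-leaf tree)."""
    from clifitree.forest import BaggedEnsemble
    from clifitree.tree import DecisionTree

    stump = {
        "mode": "classification", "class_list": ["a", "b"], "n_features": 1,
        "root_class_counts": [["a", 1], ["b", 1]],
        "nodes": [
            {"node_id": 0, "left": 1, "right": 2, "split": {
                "feature_index": 0, "neighbourhood": [0], "loadings": [1.0],
                "center": [0.0], "threshold": 0.5,
                "class_counts_parent": [["a", 1], ["b", 1]],
                "class_counts_left": [["a", 1], ["b", 0]],
                "class_counts_right": [["a", 0], ["b", 1]],
                "impurity_decrease": 0.5}},
            {"node_id": 1, "left": -1, "right": -1,
             "leaf": {"class_counts": [["a", 1]], "value": None}},
            {"node_id": 2, "left": -1, "right": -1,
             "leaf": {"class_counts": [["b", 1]], "value": None}},
        ],
    }
    single_leaf = {
        "mode": "classification", "class_list": ["a", "b"], "n_features": 1,
        "root_class_counts": [["a", 1], ["b", 1]],
        "nodes": [{"node_id": 0, "left": -1, "right": -1,
                   "leaf": {"class_counts": [["a", 1], ["b", 1]], "value": None}}],
    }
    return BaggedEnsemble(
        trees=[DecisionTree.from_dict(stump), DecisionTree.from_dict(single_leaf)],
        per_tree_sample_indices=[np.array([0, 1]), np.array([0, 1])],
        class_list=["a", "b"],
        params=TreeParams(),
        n_trees=2,
        sample_fraction=1.0,
    )
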