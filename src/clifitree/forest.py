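"""Bagged tree ensembles: Random Forest and the LAVASET latent-split variant.

Each tree is grown on an independent random subsample of the training data
(80 % without replacement by default).  Passing a neighbourhood index turns
the forest into a LAVASET model whose trees split on first-principal-
component scores of graph neighbourhoods; without one it is a plain RF.
Prediction is by majority vote with a deterministic tie-break on class
order.  The ensemble also exposes the classical proximity matrix — the
fraction of trees in which two samples share a leaf — used downstream for
embedding sample similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tree import DecisionTree, LabeledDataset, TreeParams, apply_tree, grow_tree

__all__ = [
    "BaggedEnsemble",
    "fit_bagged_ensemble",
    "predict_majority",
    "proximity_matrix",
]


@dataclass
class BaggedEnsemble:
    trees: list[DecisionTree]
    per_tree_sample_indices: list[np.ndarray]
    class_list: list
    params: TreeParams
    n_trees: int
    sample_fraction: float
    is_lava: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": "bagged",
            "is_lava": self.is_lava,
            "class_list": list(self.class_list),
            "n_trees": self.n_trees,
            "sample_fraction": self.sample_fraction,
            "params": {
                "mode": self.params.mode,
                "max_features": self.params.max_features,
                "min_samples_split": self.params.min_samples_split,
                "rng_seed": self.params.rng_seed,
            },
            "per_tree_sample_indices": [ix.tolist() for ix in self.per_tree_sample_indices],
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaggedEnsemble":
        return cls(
            trees=[DecisionTree.from_dict(t) for t in d["trees"]],
            per_tree_sample_indices=[np.asarray(ix) for ix in d["per_tree_sample_indices"]],
            class_list=list(d["class_list"]),
            params=TreeParams(**d["params"]),
            n_trees=d["n_trees"],
            sample_fraction=d["sample_fraction"],
            is_lava=d.get("is_lava", False),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "BaggedEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_bagged_ensemble(
    dataset: LabeledDataset,
    params: TreeParams,
    n_trees: int = 150,
    sample_fraction: float = 0.8,
    neighbourhoods: Sequence[Sequence[int]] | None = None,
    seed: int = 0,
    replace: bool = False,
) -> BaggedEnsemble:
    """Fit an RF (no neighbourhoods) or LAVASET (with neighbourhoods) model.

    Each tree draws ``ceil(sample_fraction * n)`` samples without replacement
    (set ``replace=True`` for a classic bootstrap) and grows with per-node
    candidate-feature subsampling controlled by ``params.max_features``.
    Per-tree randomness is derived from ``seed`` through spawned seed
    sequences, so results do not depend on execution order.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError("sample_fraction must be in (0, 1]")
    n = dataset.n_samples
    size = int(np.ceil(sample_fraction * n))
    class_list = dataset.classes()
    children = np.random.SeedSequence(seed).spawn(n_trees)

    trees: list[DecisionTree] = []
    indices: list[np.ndarray] = []
    for t in range(n_trees):
        rng = np.random.default_rng(children[t])
        idx = np.sort(rng.choice(n, size=size, replace=replace))
        sub = LabeledDataset(
            dataset.X[idx],
            dataset.y[idx],
            feature_names=list(dataset.feature_names),
            sample_ids=[dataset.sample_ids[i] for i in idx],
        )
        tree = grow_tree(
            sub, params, neighbourhoods, class_list=class_list, rng=rng
        )
        trees.append(tree)
        indices.append(idx)
    return BaggedEnsemble(
        trees=trees,
        per_tree_sample_indices=indices,
        class_list=class_list,
        params=params,
        n_trees=n_trees,
        sample_fraction=sample_fraction,
        is_lava=neighbourhoods is not None,
    )


def predict_majority(
    ensemble: BaggedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over trees.

    Returns ``(labels, vote_fractions)``; fractions are ordered by
    ``ensemble.class_list`` and sum to 1 per sample.  Ties go to the class
    earliest in ``class_list``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    K = len(ensemble.class_list)
    pos = {c: k for k, c in enumerate(ensemble.class_list)}
    votes = np.zeros((n, K))
    for tree in ensemble.trees:
        _, preds = apply_tree(tree, X)
        for i, c in enumerate(preds):
            votes[i, pos[c]] += 1.0
    fractions = votes / votes.sum(axis=1, keepdims=True)
    labels = np.array(
        [ensemble.class_list[int(np.argmax(votes[i]))] for i in range(n)],
        dtype=object,
    )
    return labels, fractions


def proximity_matrix(ensemble: BaggedEnsemble, X: np.ndarray) -> np.ndarray:
    """Fraction of trees in which sample pairs co-occupy a leaf.

    Symmetric with unit diagonal, entries in ``[0, 1]``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    prox = np.zeros((n, n))
    for tree in ensemble.trees:
        leaf_ids, _ = apply_tree(tree, X)
        prox += (leaf_ids[:, None] == leaf_ids[None, :]).astype(float)
    prox /= len(ensemble.trees)
    return prox
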