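"""One-vs-all multiclass gradient-boosted regression trees (GBDT/LAVABOOST).

The K-class problem is reduced to K coupled binary problems.  Score
functions F(x) start at zero for every class; each round converts scores to
probabilities through a softmax link, computes per-class pseudo-residuals
(one-hot minus probability), and fits one regression tree per class to its
residual column.  Leaf predictions are replaced by the Newton-style update

    gamma = ((K-1)/K) * sum(r) / sum(|r| (1 - |r|))

and applied with shrinkage ``F += eta * gamma``.  When a neighbourhood index
is supplied the regression trees use LAVA latent splits (LAVABOOST);
otherwise they are ordinary CART trees (GBDT).

Because a boosted tree regresses on residuals, its split counts cannot be
tallied by true class directly: each distinct pseudo-residual value in the
tree's training sample becomes an *error label*, and every split records
counts per error label.  The per-class mixing weights S_hi (share of class-h
samples carrying error label i) are stored alongside each tree so the CLIFI
module can reconcile error-label importances back to true classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tree import DecisionTree, LabeledDataset, TreeParams, apply_tree, grow_tree

__all__ = [
    "BoosterModel",
    "BoostedTree",
    "class_probabilities",
    "pseudo_residuals",
    "leaf_gamma",
    "assign_error_labels",
    "fit_boosted_ensemble",
    "predict_boosted",
]

ERROR_LABEL_DECIMALS = 10  # residuals rounded to this before grouping


@dataclass
class BoostedTree:
    """One regression tree of the ensemble plus its error-label bookkeeping.

    ``error_label_values`` maps integer label ids to the rounded residual
    value they stand for; ``class_label_weights`` maps each true class h to
    ``{label_id: S_hi}`` with the S_hi summing to 1 within each class.
    """

    tree: DecisionTree
    round_index: int
    class_index: int
    error_label_values: dict[int, float]
    class_label_weights: dict


@dataclass
class BoosterModel:
    class_list: list
    learning_rate: float
    n_rounds: int
    trees: list[list[BoostedTree]]  # [round][class]
    train_accuracy_path: list[float] = field(default_factory=list)
    n_features: int = 0
    is_lava: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": "boosted",
            "is_lava": self.is_lava,
            "class_list": list(self.class_list),
            "learning_rate": self.learning_rate,
            "n_rounds": self.n_rounds,
            "n_features": self.n_features,
            "train_accuracy_path": self.train_accuracy_path,
            "trees": [
                [
                    {
                        "tree": bt.tree.to_dict(),
                        "round_index": bt.round_index,
                        "class_index": bt.class_index,
                        "error_label_values": [
                            [int(k), float(v)] for k, v in bt.error_label_values.items()
                        ],
                        "class_label_weights": [
                            [h, [[int(i), float(s)] for i, s in w.items()]]
                            for h, w in bt.class_label_weights.items()
                        ],
                    }
                    for bt in row
                ]
                for row in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoosterModel":
        trees = [
            [
                BoostedTree(
                    tree=DecisionTree.from_dict(bt["tree"]),
                    round_index=bt["round_index"],
                    class_index=bt["class_index"],
                    error_label_values={k: v for k, v in bt["error_label_values"]},
                    class_label_weights={
                        h: {i: s for i, s in w} for h, w in bt["class_label_weights"]
                    },
                )
                for bt in row
            ]
            for row in d["trees"]
        ]
        return cls(
            class_list=list(d["class_list"]),
            learning_rate=d["learning_rate"],
            n_rounds=d["n_rounds"],
            trees=trees,
            train_accuracy_path=d.get("train_accuracy_path", []),
            n_features=d.get("n_features", 0),
            is_lava=d.get("is_lava", False),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "BoosterModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def class_probabilities(F: np.ndarray) -> np.ndarray:
    """Softmax of score rows, computed with a max shift for stability."""
    F = np.asarray(F, dtype=float)
    one_d = F.ndim == 1
    if one_d:
        F = F[None, :]
    shifted = F - F.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    P = e / e.sum(axis=1, keepdims=True)
    return P[0] if one_d else P


def pseudo_residuals(one_hot_y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Negative gradient of the multinomial deviance: one-hot minus softmax."""
    one_hot_y = np.asarray(one_hot_y, dtype=float)
    P = np.asarray(P, dtype=float)
    if one_hot_y.shape != P.shape:
        raise ValueError("shape mismatch between one-hot labels and probabilities")
    return one_hot_y - P


def leaf_gamma(residuals_in_leaf: np.ndarray, K: int) -> float:
    """Per-leaf Newton update ``((K-1)/K) * sum(r) / sum(|r|(1-|r|))``.

    Returns 0 (with a warning) when the denominator vanishes.
    """
    r = np.asarray(residuals_in_leaf, dtype=float)
    if r.size == 0:
        raise ValueError("empty leaf")
    denom = np.sum(np.abs(r) * (1.0 - np.abs(r)))
    if denom <= 0.0:
        if np.any(r != 0.0):
            warnings.warn("zero denominator in leaf update; using gamma=0")
        return 0.0
    return float((K - 1) / K * r.sum() / denom)


def assign_error_labels(
    residual_column: np.ndarray, true_labels: np.ndarray
) -> tuple[np.ndarray, dict[int, float], dict]:
    """Group samples by rounded residual value and weight labels per class.

    Residuals are rounded to 10 decimals; each distinct rounded value is an
    error label (ids assigned in ascending value order).  Returns
    ``(label_ids, label_values, class_label_weights)`` where
    ``class_label_weights[h][i]`` is the share S_hi of class-h samples with
    label i (summing to 1 within each class).
    """
    r = np.round(np.asarray(residual_column, dtype=float), ERROR_LABEL_DECIMALS)
    # avoid -0.0 / 0.0 splitting into two labels
    r = r + 0.0
    values, label_ids = np.unique(r, return_inverse=True)
    label_values = {int(i): float(v) for i, v in enumerate(values)}
    true_labels = np.asarray(true_labels)
    weights: dict = {}
    for h in np.unique(true_labels).tolist():
        mask = true_labels == h
        ids, counts = np.unique(label_ids[mask], return_counts=True)
        total = counts.sum()
        weights[h] = {int(i): float(c) / total for i, c in zip(ids, counts)}
    return label_ids.astype(np.intp), label_values, weights


def fit_boosted_ensemble(
    dataset: LabeledDataset,
    params: TreeParams,
    n_rounds: int = 130,
    learning_rate: float = 0.1,
    neighbourhoods: Sequence[Sequence[int]] | None = None,
    seed: int = 0,
) -> BoosterModel:
    """Fit a GBDT (no neighbourhoods) or LAVABOOST (with neighbourhoods).

    Scores are initialised to zero; all samples enter every tree (no row
    subsampling), while candidate features per split follow
    ``params.max_features``.  Per-(round, class) tree randomness is spawned
    from ``seed``.
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    X, y = dataset.X, dataset.y
    n = dataset.n_samples
    class_list = dataset.classes()
    K = len(class_list)
    one_hot = np.zeros((n, K))
    for k, c in enumerate(class_list):
        one_hot[y == c, k] = 1.0

    tree_params = TreeParams(
        mode="regression",
        max_features=params.max_features,
        min_samples_split=params.min_samples_split,
        rng_seed=params.rng_seed,
    )
    seeds = np.random.SeedSequence(seed).spawn(max(n_rounds, 1) * K)

    F = np.zeros((n, K))
    rounds: list[list[BoostedTree]] = []
    acc_path: list[float] = []
    for m in range(n_rounds):
        P = class_probabilities(F)
        R = pseudo_residuals(one_hot, P)
        row: list[BoostedTree] = []
        for k in range(K):
            r = R[:, k]
            label_ids, label_values, weights = assign_error_labels(r, y)
            sub = LabeledDataset(
                X, r, feature_names=list(dataset.feature_names),
                sample_ids=list(dataset.sample_ids),
            )
            rng = np.random.default_rng(seeds[m * K + k])
            tree = grow_tree(
                sub,
                tree_params,
                neighbourhoods,
                count_labels=label_ids,
                class_list=sorted(label_values.keys()),
                rng=rng,
            )
            leaf_ids, _ = apply_tree(tree, X)
            for leaf in tree.leaves():
                members = leaf_ids == leaf.node_id
                gamma = leaf_gamma(r[members], K) if members.any() else 0.0
                leaf.value = gamma
            F[:, k] += learning_rate * np.array(
                [tree.nodes[l].value for l in leaf_ids], dtype=float
            )
            row.append(
                BoostedTree(
                    tree=tree,
                    round_index=m,
                    class_index=k,
                    error_label_values=label_values,
                    class_label_weights=weights,
                )
            )
        rounds.append(row)
        train_pred = np.array(
            [class_list[int(j)] for j in np.argmax(F, axis=1)], dtype=object
        )
        acc_path.append(float(np.mean(train_pred == y)))
    return BoosterModel(
        class_list=class_list,
        learning_rate=learning_rate,
        n_rounds=n_rounds,
        trees=rounds,
        train_accuracy_path=acc_path,
        n_features=dataset.n_features,
        is_lava=neighbourhoods is not None,
    )


def predict_boosted(
    model: BoosterModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate shrunken tree outputs from zero scores and softmax them.

    Returns ``(labels, probabilities)``; argmax ties break to the class
    earliest in ``class_list`` (so an empty model predicts the first class).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    K = len(model.class_list)
    F = np.zeros((n, K))
    for row in model.trees:
        for bt in row:
            _, values = apply_tree(bt.tree, X)
            F[:, bt.class_index] += model.learning_rate * values
    P = class_probabilities(F)
    labels = np.array(
        [model.class_list[int(np.argmax(F[i]))] for i in range(n)], dtype=object
    )
    return labels, P
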