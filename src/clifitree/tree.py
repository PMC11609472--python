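"""CART-style decision trees with optional latent-variable (LAVA) splits.

A tree is grown on a :class:`LabeledDataset` by recursive binary splitting.
In plain mode each candidate split thresholds a raw feature column.  In LAVA
mode a candidate feature is replaced by the first principal-component score
of the feature together with its graph neighbours (computed on the samples
present at the node), so the split is oblique in the original feature space
while remaining a single-threshold decision on the latent score.  The loading
vector is retained on the node for routing and for attributing importance
back to the original features.

Every internal node stores a complete :class:`SplitRecord`, including the
per-class sample counts of the parent and both children; these counts are the
raw material of the CLIFI directional importance computed in
:mod:`clifitree.clifi`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LabeledDataset",
    "TreeParams",
    "SplitRecord",
    "DecisionTree",
    "gini_impurity",
    "find_best_split",
    "lava_latent_scores",
    "grow_tree",
    "apply_tree",
]


class DegenerateNodeError(ValueError):
    """Raised when a node carries no samples (all-zero class counts)."""


@dataclass
class LabeledDataset:
    """A samples × features matrix with labels and names.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix, no missing values.
    y : ndarray of shape (n_samples,)
        Categorical labels (classification) or real targets (regression).
    feature_names : sequence of str
        Unique names, one per column.
    sample_ids : sequence of str, optional
        Defaults to ``s0000 ...``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if len(self.y) != n:
            raise ValueError("y length does not match X")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match X")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match X")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def classes(self) -> list:
        return sorted(np.unique(self.y).tolist())


@dataclass
class TreeParams:
    """Growth parameters shared by all ensemble variants.

    ``max_features`` is the number of candidate anchor features drawn without
    replacement at every node: ``"sqrt"`` (rounded up), ``"all"``, or an
    explicit integer in ``[1, p]``.
    """

    mode: str = "classification"
    max_features: str | int = "sqrt"
    min_samples_split: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if isinstance(self.max_features, str):
            if self.max_features not in ("sqrt", "all"):
                raise ValueError(f"unknown max_features {self.max_features!r}")
        elif int(self.max_features) < 1:
            raise ValueError("integer max_features must be >= 1")

    def resolve_max_features(self, p: int) -> int:
        if self.max_features == "sqrt":
            return min(p, int(np.ceil(np.sqrt(p))))
        if self.max_features == "all":
            return p
        m = int(self.max_features)
        if m > p:
            raise ValueError(f"max_features {m} exceeds feature count {p}")
        return m


@dataclass
class SplitRecord:
    """One internal node: the oriented hyperplane and its class bookkeeping.

    ``neighbourhood`` holds the original feature indices entering the latent
    score (length 1 with ``loadings == [1.0]`` and ``center == [0.0]`` for a
    plain axis-aligned split).  Class counts are dicts keyed by class label
    (true classes in bagged models, error labels in boosted trees).
    """

    node_id: int
    feature_index: int
    neighbourhood: tuple[int, ...]
    loadings: np.ndarray
    center: np.ndarray
    threshold: float
    class_counts_parent: dict
    class_counts_left: dict
    class_counts_right: dict
    impurity_decrease: float

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        for c, n in self.class_counts_parent.items():
            nl = self.class_counts_left.get(c, 0)
            nr = self.class_counts_right.get(c, 0)
            if nl + nr != n:
                raise ValueError(
                    f"child counts {nl}+{nr} != parent count {n} for class {c!r}"
                )


@dataclass
class _Node:
    node_id: int
    split: SplitRecord | None = None  # None at leaves
    left: int = -1
    right: int = -1
    # leaf payload
    class_counts: dict | None = None
    value: float | None = None
    train_indices: np.ndarray | None = None


@dataclass
class DecisionTree:
    """A grown tree: nodes indexed by id, root at 0."""

    mode: str
    nodes: dict[int, _Node]
    root_class_counts: dict
    class_list: list
    n_features: int

    def internal_nodes(self) -> list[_Node]:
        return [nd for nd in self.nodes.values() if nd.split is not None]

    def leaves(self) -> list[_Node]:
        return [nd for nd in self.nodes.values() if nd.split is None]

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out_nodes = []
        for nd in self.nodes.values():
            d: dict = {"node_id": nd.node_id, "left": nd.left, "right": nd.right}
            if nd.split is not None:
                s = nd.split
                d["split"] = {
                    "feature_index": int(s.feature_index),
                    "neighbourhood": list(map(int, s.neighbourhood)),
                    "loadings": s.loadings.tolist(),
                    "center": s.center.tolist(),
                    "threshold": float(s.threshold),
                    "class_counts_parent": _counts_to_json(s.class_counts_parent),
                    "class_counts_left": _counts_to_json(s.class_counts_left),
                    "class_counts_right": _counts_to_json(s.class_counts_right),
                    "impurity_decrease": float(s.impurity_decrease),
                }
            else:
                d["leaf"] = {
                    "class_counts": _counts_to_json(nd.class_counts),
                    "value": nd.value,
                }
            out_nodes.append(d)
        return {
            "mode": self.mode,
            "class_list": list(self.class_list),
            "n_features": self.n_features,
            "root_class_counts": _counts_to_json(self.root_class_counts),
            "nodes": out_nodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        nodes: dict[int, _Node] = {}
        for nd in d["nodes"]:
            if "split" in nd:
                s = nd["split"]
                split = SplitRecord(
                    node_id=nd["node_id"],
                    feature_index=s["feature_index"],
                    neighbourhood=tuple(s["neighbourhood"]),
                    loadings=np.asarray(s["loadings"]),
                    center=np.asarray(s["center"]),
                    threshold=s["threshold"],
                    class_counts_parent=_counts_from_json(s["class_counts_parent"]),
                    class_counts_left=_counts_from_json(s["class_counts_left"]),
                    class_counts_right=_counts_from_json(s["class_counts_right"]),
                    impurity_decrease=s["impurity_decrease"],
                )
                nodes[nd["node_id"]] = _Node(
                    nd["node_id"], split=split, left=nd["left"], right=nd["right"]
                )
            else:
                leaf = nd["leaf"]
                nodes[nd["node_id"]] = _Node(
                    nd["node_id"],
                    class_counts=_counts_from_json(leaf["class_counts"]),
                    value=leaf["value"],
                )
        return cls(
            mode=d["mode"],
            nodes=nodes,
            root_class_counts=_counts_from_json(d["root_class_counts"]),
            class_list=list(d["class_list"]),
            n_features=d["n_features"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DecisionTree":
        return cls.from_dict(json.loads(s))


def _counts_to_json(counts: dict | None) -> list | None:
    if counts is None:
        return None
    return [[k, int(v)] for k, v in counts.items()]


def _counts_from_json(items: list | None) -> dict | None:
    if items is None:
        return None
    return {k: v for k, v in items}


# ---------------------------------------------------------------------------
# impurities and split search
# ---------------------------------------------------------------------------

def gini_impurity(class_counts: Sequence[float] | np.ndarray) -> float:
    """Gini impurity ``1 - sum_k (n_k/n)^2`` of a count vector.

    Zero iff the node is pure; bounded above by ``1 - 1/K``.
    """
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative class count")
    n = counts.sum()
    if n == 0:
        raise DegenerateNodeError("all-zero class counts")
    frac = counts / n
    return float(1.0 - (frac**2).sum())


def find_best_split(
    column: np.ndarray,
    targets: np.ndarray,
    mode: str = "classification",
) -> tuple[float, float] | None:
    """Best single-threshold split of ``column`` for ``targets``.

    Thresholds are midpoints of adjacent sorted distinct column values; the
    returned ``gain`` is parent impurity minus the size-weighted child
    impurity (Gini for classification, mean sum-of-squares for regression).
    Returns ``None`` when no valid split exists (constant column, or no
    threshold with positive gain).  Ties in gain break to the lowest
    threshold.
    """
    x = np.asarray(column, dtype=float)
    n = x.shape[0]
    if n < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cut = np.nonzero(xs[1:] > xs[:-1])[0]  # split after position i
    if cut.size == 0:
        return None
    n_left = (cut + 1).astype(float)
    n_right = n - n_left

    if mode == "classification":
        codes, _ = pd_factorize_sorted(np.asarray(targets)[order])
        K = codes.max() + 1
        onehot = np.zeros((n, K))
        onehot[np.arange(n), codes] = 1.0
        cum = np.cumsum(onehot, axis=0)
        left = cum[cut]
        total = cum[-1]
        right = total - left
        g_left = 1.0 - ((left / n_left[:, None]) ** 2).sum(axis=1)
        g_right = 1.0 - ((right / n_right[:, None]) ** 2).sum(axis=1)
        g_parent = 1.0 - ((total / n) ** 2).sum()
        gain = g_parent - (n_left * g_left + n_right * g_right) / n
    elif mode == "regression":
        t = np.asarray(targets, dtype=float)[order]
        s1 = np.cumsum(t)
        s2 = np.cumsum(t * t)
        sse_left = s2[cut] - s1[cut] ** 2 / n_left
        sse_right = (s2[-1] - s2[cut]) - (s1[-1] - s1[cut]) ** 2 / n_right
        sse_parent = s2[-1] - s1[-1] ** 2 / n
        # mean SSE keeps the gain on the same intensive scale as Gini
        gain = (sse_parent - sse_left - sse_right) / n
    else:  # pragma: no cover - guarded by TreeParams
        raise ValueError(f"unknown mode {mode!r}")

    best = int(np.argmax(gain))  # first max = lowest threshold
    if gain[best] <= 0.0:
        return None
    i = cut[best]
    threshold = (xs[i] + xs[i + 1]) / 2.0
    return float(threshold), float(gain[best])


def pd_factorize_sorted(values: np.ndarray) -> tuple[np.ndarray, list]:
    """Integer-encode labels against their sorted unique values."""
    uniq = np.unique(values)
    codes = np.searchsorted(uniq, values)
    return codes.astype(np.intp), uniq.tolist()


# ---------------------------------------------------------------------------
# latent (LAVA) scores
# ---------------------------------------------------------------------------

def lava_latent_scores(
    X_node: np.ndarray, anchor_position: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First principal-component score of a node-local feature neighbourhood.

    Columns are centered (not variance-scaled); the loading vector is the
    first right singular vector of the centered submatrix, with its sign
    fixed so the largest-magnitude element is positive.  A zero-variance
    submatrix degrades to a unit loading on the anchor column with all-zero
    scores.

    Returns ``(scores, loadings, center)``.
    """
    X_node = np.asarray(X_node, dtype=float)
    if X_node.ndim == 1:
        X_node = X_node[:, None]
    n, q = X_node.shape
    center = X_node.mean(axis=0)
    Xc = X_node - center
    if not np.any(np.abs(Xc) > 0):
        loadings = np.zeros(q)
        loadings[anchor_position] = 1.0
        return np.zeros(n), loadings, center
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    imax = int(np.argmax(np.abs(loadings)))
    if loadings[imax] < 0:
        loadings = -loadings
    scores = Xc @ loadings
    return scores, loadings, center


# ---------------------------------------------------------------------------
# growth and application
# ---------------------------------------------------------------------------

def grow_tree(
    dataset: LabeledDataset,
    params: TreeParams,
    neighbourhoods: Sequence[Sequence[int]] | None = None,
    *,
    count_labels: np.ndarray | None = None,
    class_list: list | None = None,
    rng: np.random.Generator | None = None,
) -> DecisionTree:
    """Grow one CART tree, optionally with LAVA latent splits.

    ``count_labels`` are the labels tallied into every SplitRecord (defaults
    to ``dataset.y``; boosted regression trees pass error-label ids here).
    ``neighbourhoods`` maps each feature index to the ordered feature indices
    of its latent neighbourhood; a size-1 neighbourhood is an ordinary
    axis-aligned split.  Recursion stops at purity (or zero target variance),
    at ``min_samples_split``, or when no sampled candidate yields a positive
    gain.
    """
    X, y = dataset.X, dataset.y
    n, p = X.shape
    if neighbourhoods is not None and len(neighbourhoods) != p:
        raise ValueError("neighbourhoods must cover every feature")
    if count_labels is None:
        if params.mode == "regression":
            raise ValueError("regression trees need explicit count_labels")
        count_labels = y
    count_labels = np.asarray(count_labels)
    if class_list is None:
        class_list = sorted(np.unique(count_labels).tolist())
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    m = params.resolve_max_features(p)

    nodes: dict[int, _Node] = {}
    counter = [0]

    def counts_of(idx: np.ndarray) -> dict:
        vals, cnt = np.unique(count_labels[idx], return_counts=True)
        return {v: int(c) for v, c in zip(vals.tolist(), cnt.tolist())}

    def make_leaf(idx: np.ndarray) -> int:
        nid = counter[0]
        counter[0] += 1
        cc = counts_of(idx)
        if params.mode == "classification":
            value = None
        else:
            value = float(np.mean(y[idx].astype(float)))
        nodes[nid] = _Node(nid, class_counts=cc, value=value, train_indices=idx)
        return nid

    def is_pure(idx: np.ndarray) -> bool:
        if params.mode == "classification":
            return np.unique(y[idx]).size == 1
        t = y[idx].astype(float)
        return bool(np.all(t == t[0]))

    def build(idx: np.ndarray) -> int:
        if idx.size < params.min_samples_split or is_pure(idx):
            return make_leaf(idx)
        candidates = np.sort(rng.choice(p, size=m, replace=False))
        best: tuple[float, float, int, tuple, np.ndarray, np.ndarray, np.ndarray] | None = None
        for j in candidates:
            neigh = (
                tuple(int(f) for f in neighbourhoods[j])
                if neighbourhoods is not None
                else (int(j),)
            )
            if len(neigh) == 1:
                # plain axis-aligned split (identity neighbourhood degrades
                # exactly to RF behaviour)
                scores = X[idx, neigh[0]]
                loadings = np.array([1.0])
                center = np.array([0.0])
            else:
                anchor_pos = neigh.index(int(j))
                scores, loadings, center = lava_latent_scores(
                    X[np.ix_(idx, neigh)], anchor_position=anchor_pos
                )
            found = find_best_split(scores, y[idx], params.mode)
            if found is None:
                continue
            threshold, gain = found
            if best is None or gain > best[0]:
                best = (gain, threshold, int(j), neigh, loadings, center, scores)
        if best is None:
            return make_leaf(idx)
        gain, threshold, j, neigh, loadings, center, scores = best
        left_mask = scores <= threshold
        idx_left = idx[left_mask]
        idx_right = idx[~left_mask]

        nid = counter[0]
        counter[0] += 1
        node = _Node(nid)
        nodes[nid] = node
        node.left = build(idx_left)
        node.right = build(idx_right)
        node.split = SplitRecord(
            node_id=nid,
            feature_index=j,
            neighbourhood=neigh,
            loadings=loadings,
            center=center,
            threshold=threshold,
            class_counts_parent=counts_of(idx),
            class_counts_left=counts_of(idx_left),
            class_counts_right=counts_of(idx_right),
            impurity_decrease=gain,
        )
        return nid

    root_idx = np.arange(n)
    root_counts = {
        v: int(c)
        for v, c in zip(*[a.tolist() for a in np.unique(count_labels, return_counts=True)])
    }
    build(root_idx)
    return DecisionTree(
        mode=params.mode,
        nodes=nodes,
        root_class_counts=root_counts,
        class_list=class_list,
        n_features=p,
    )


def apply_tree(tree: DecisionTree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Route samples through the tree.

    Returns ``(leaf_ids, predictions)`` where predictions are majority
    classes (classification, ties to the first class in ``class_list``) or
    leaf values (regression).  LAVA nodes re-apply the stored center and
    loadings before the threshold comparison.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != tree.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, tree expects {tree.n_features}"
        )
    n = X.shape[0]
    leaf_ids = np.empty(n, dtype=np.intp)
    for i in range(n):
        nid = 0
        node = tree.nodes[nid]
        while node.split is not None:
            s = node.split
            z = float((X[i, list(s.neighbourhood)] - s.center) @ s.loadings)
            nid = node.left if z <= s.threshold else node.right
            node = tree.nodes[nid]
        leaf_ids[i] = nid
    if tree.mode == "classification":
        preds = np.empty(n, dtype=object)
        for i in range(n):
            cc = tree.nodes[leaf_ids[i]].class_counts or {}
            best_c, best_n = None, -1
            for c in tree.class_list:
                v = cc.get(c, 0)
                if v > best_n:
                    best_c, best_n = c, v
            preds[i] = best_c
        return leaf_ids, preds
    values = np.array([tree.nodes[leaf_ids[i]].value for i in range(n)], dtype=float)
    return leaf_ids, values
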