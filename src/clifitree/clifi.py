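"""CLIFI: class-based integrated directional feature importance.

CLIFI scores every internal split of a tree ensemble, per class, with a
signed value in [-1, 1] derived from a G-test of the class's left/right
child counts against an even split of its parent count:

    M1 = 2 L ln(2L/P),   M2 = 2 R ln(2R/P)

    CLIFI = (R ln(2R/P) + L ln(2L/P)) / (A ln 2)
            * sign(R ln(2R/P) - L ln(2L/P))

where L, R, P are the class's left/right/parent counts at the split and A
is the class's count at the tree root (its training subsample).  The G-test
part, (M1 + M2) / 2, is normalised by the perfect-split value P ln 2 and
scaled by P/A, so a split at the root that sends an entire class one way
scores exactly +1 (right) or -1 (left), and an exactly even split scores 0.
Positive values mean the class concentrates above the split threshold.

For latent (LAVA) splits the split-level value is distributed over the
neighbourhood's original features proportionally to |loading| (normalised
to sum 1), with the contribution's sign flipped for negative loadings so
directionality stays congruent with the raw feature values.

Boosted trees regress on pseudo-residuals, so their splits are scored per
*error label* and reconciled to true classes by the weighted sum
CLIFI_h = sum_i S_hi * CLIFI_i over the labels i carried by class h.

Per-(feature, class) values are summed over all splits and trees into the
aggregated aCLIFI matrix; dividing by the largest absolute entry gives the
normalised naCLIFI used to compare models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .boost import BoosterModel
from .forest import BaggedEnsemble

__all__ = [
    "CategoricalFrequencies",
    "SplitClassCounts",
    "CLIFITable",
    "g_test",
    "partial_g",
    "clifi_for_split",
    "distribute_to_original_features",
    "clifi_boosting_rescale",
    "collect_clifi",
    "aggregate_and_normalize",
    "select_top_features",
    "class_difference_tests",
]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class CategoricalFrequencies:
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.observed.shape != self.expected.shape:
            raise ValueError("observed/expected shape mismatch")
        if (self.observed < 0).any() or (self.expected < 0).any():
            raise ValueError("negative frequency")
        if self.expected.sum() <= 0:
            raise ValueError("expected frequencies sum to zero")


@dataclass
class SplitClassCounts:
    """Counts for one class at one split: left, right, parent, ancestor."""

    left: float
    right: float
    parent: float
    ancestor: float

    def __post_init__(self) -> None:
        if min(self.left, self.right, self.parent, self.ancestor) < 0:
            raise ValueError("negative count")
        if abs(self.left + self.right - self.parent) > 1e-9:
            raise ValueError(
                f"left {self.left} + right {self.right} != parent {self.parent}"
            )
        if self.parent > self.ancestor + 1e-9:
            raise ValueError("parent count exceeds ancestor count")


@dataclass
class CLIFITable:
    """All split-level CLIFI records plus aggregated matrices.

    ``records`` has columns (tree_id, node_id, feature, class, value);
    ``aclifi``/``naclifi`` are features × classes DataFrames.
    """

    records: pd.DataFrame
    feature_names: list[str]
    class_list: list
    aclifi: pd.DataFrame | None = None
    naclifi: pd.DataFrame | None = None


def g_test(freqs: CategoricalFrequencies) -> float:
    """Likelihood-ratio goodness of fit: ``2 sum_{O_i>0} O_i ln(O_i/E_i)``."""
    O, E = freqs.observed, freqs.expected
    mask = O > 0
    if (E[mask] <= 0).any():
        raise ValueError("observed count with zero expected count")
    return float(2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask])))


def partial_g(child_count: float, parent_count: float) -> float:
    """One child's G-test term against an even split: ``2 c ln(2c/P)``.

    Zero-count children contribute 0 (their term is dropped).
    """
    if parent_count <= 0:
        raise ValueError("parent count must be positive")
    if child_count < 0 or child_count > parent_count:
        raise ValueError("child count outside [0, parent]")
    if child_count == 0:
        return 0.0
    return float(2.0 * child_count * np.log(2.0 * child_count / parent_count))


def clifi_for_split(counts: SplitClassCounts) -> float:
    """Signed, ancestor-normalised split importance for one class.

    Zero when the class is absent from the split (parent count 0) or the
    split is exactly even; bounded by ``P/A <= 1`` in magnitude.
    """
    L, R, P, A = counts.left, counts.right, counts.parent, counts.ancestor
    if P == 0:
        return 0.0
    if A <= 0:
        raise ValueError("ancestor count must be positive for a scored class")
    m1 = partial_g(L, P)
    m2 = partial_g(R, P)
    magnitude = (m1 + m2) / (2.0 * A * LN2)
    return float(magnitude * np.sign(m2 - m1))


def distribute_to_original_features(
    split_value: float,
    loadings: np.ndarray,
    neighbourhood: tuple[int, ...],
    signed: bool = True,
) -> dict[int, float]:
    """Spread a split-level value over the neighbourhood's features.

    Weights are ``|loading| / sum |loadings|``; with ``signed=True`` (the
    default) each contribution also takes the sign of its loading, keeping
    the per-feature direction congruent with raw feature values.  The
    absolute contributions always sum to ``|split_value|``.
    """
    loadings = np.asarray(loadings, dtype=float)
    total = np.abs(loadings).sum()
    if total == 0:
        logger.debug("all-zero loadings; contribution skipped")
        return {}
    weights = np.abs(loadings) / total
    out: dict[int, float] = {}
    for f, w, l in zip(neighbourhood, weights, loadings):
        v = split_value * w
        if signed and l < 0:
            v = -v
        out[int(f)] = out.get(int(f), 0.0) + v
    return out


def clifi_boosting_rescale(
    per_label_values: dict[int, float], weights: dict[int, float]
) -> float:
    """Mix error-label CLIFI values into a class value: ``sum_i S_hi v_i``."""
    s = sum(weights.values())
    if abs(s - 1.0) > 1e-8:
        raise ValueError(f"class label weights sum to {s}, expected 1")
    out = 0.0
    for label, value in per_label_values.items():
        if label not in weights:
            raise ValueError(f"error label {label} missing from class weights")
        out += weights[label] * value
    return out


# ---------------------------------------------------------------------------
# collection over fitted models
# ---------------------------------------------------------------------------

def collect_clifi(
    model: BaggedEnsemble | BoosterModel,
    feature_names: list[str] | None = None,
    signed_loadings: bool = True,
) -> CLIFITable:
    """Walk every internal node of a fitted model and build the CLIFI table.

    Bagged models score true-class counts directly; boosted models score
    error-label counts and reconcile them to true classes through the stored
    S_hi weights.  The result is aggregated and normalised.
    """
    if isinstance(model, BaggedEnsemble):
        rows = _collect_bagged(model, signed_loadings)
        class_list = list(model.class_list)
        p = model.trees[0].n_features if model.trees else 0
    elif isinstance(model, BoosterModel):
        rows = _collect_boosted(model, signed_loadings)
        class_list = list(model.class_list)
        p = model.n_features
    else:
        raise TypeError(
            f"unsupported model type {type(model).__name__}: "
            "CLIFI needs SplitRecords with retained class counts"
        )
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    records = pd.DataFrame(
        rows, columns=["tree_id", "node_id", "feature", "class", "value"]
    )
    if len(records):
        records["feature"] = [feature_names[j] for j in records["feature"]]
    table = CLIFITable(records=records, feature_names=feature_names, class_list=class_list)
    return aggregate_and_normalize(table)


def _collect_bagged(model: BaggedEnsemble, signed: bool) -> list[tuple]:
    rows: list[tuple] = []
    for t, tree in enumerate(model.trees):
        root = tree.root_class_counts
        for node in tree.internal_nodes():
            s = node.split
            for c in model.class_list:
                P = s.class_counts_parent.get(c, 0)
                if P == 0:
                    continue
                value = clifi_for_split(
                    SplitClassCounts(
                        left=s.class_counts_left.get(c, 0),
                        right=s.class_counts_right.get(c, 0),
                        parent=P,
                        ancestor=root[c],
                    )
                )
                for f, v in distribute_to_original_features(
                    value, s.loadings, s.neighbourhood, signed
                ).items():
                    rows.append((t, s.node_id, f, c, v))
    return rows


def _collect_boosted(model: BoosterModel, signed: bool) -> list[tuple]:
    rows: list[tuple] = []
    t = 0
    for row in model.trees:
        for bt in row:
            tree = bt.tree
            root = tree.root_class_counts
            for node in tree.internal_nodes():
                s = node.split
                # per-error-label split values
                label_values: dict[int, float] = {}
                for lab, P in s.class_counts_parent.items():
                    if P == 0:
                        continue
                    label_values[lab] = clifi_for_split(
                        SplitClassCounts(
                            left=s.class_counts_left.get(lab, 0),
                            right=s.class_counts_right.get(lab, 0),
                            parent=P,
                            ancestor=root[lab],
                        )
                    )
                for h, weights in bt.class_label_weights.items():
                    present = {
                        lab: v for lab, v in label_values.items() if lab in weights
                    }
                    if not present:
                        continue
                    # labels of class h absent at this split contribute 0
                    value = sum(weights[lab] * v for lab, v in present.items())
                    for f, v in distribute_to_original_features(
                        value, s.loadings, s.neighbourhood, signed
                    ).items():
                        rows.append((t, s.node_id, f, h, v))
            t += 1
    return rows


def aggregate_and_normalize(table: CLIFITable) -> CLIFITable:
    """Sum records into the features × classes aCLIFI and max-abs normalise."""
    aclifi = pd.DataFrame(
        0.0, index=table.feature_names, columns=table.class_list
    )
    if len(table.records):
        sums = table.records.groupby(["feature", "class"])["value"].sum()
        for (f, c), v in sums.items():
            aclifi.loc[f, c] = v
    peak = float(np.abs(aclifi.to_numpy()).max()) if aclifi.size else 0.0
    if peak == 0.0:
        if len(table.records):
            warnings.warn("all aggregated CLIFI values are zero")
        naclifi = aclifi.copy()
    else:
        naclifi = aclifi / peak
    table.aclifi = aclifi
    table.naclifi = naclifi
    return table


def select_top_features(
    table: CLIFITable, cls, k: int = 10, direction: str = "positive"
) -> list[str]:
    """Top-k features for a class, filtered by the mean of same-sign values.

    Positive direction keeps features whose aggregated CLIFI strictly
    exceeds the mean of the positive values, ranked descending; negative
    direction is symmetric (strictly below the mean of negative values,
    ranked ascending).  Returns an empty list when nothing passes.
    """
    if table.aclifi is None:
        raise ValueError("table is not aggregated")
    col = table.aclifi[cls]
    if direction == "positive":
        pos = col[col > 0]
        if pos.empty:
            return []
        keep = col[col > pos.mean()].sort_values(ascending=False)
    elif direction == "negative":
        neg = col[col < 0]
        if neg.empty:
            return []
        keep = col[col < neg.mean()].sort_values(ascending=True)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return keep.index[:k].tolist()


def class_difference_tests(
    table: CLIFITable, alpha: float = 0.05, min_records: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis per feature across classes, then pairwise Mann-Whitney.

    The omnibus p-values are Benjamini-Hochberg adjusted across features;
    features significant at ``alpha`` get pairwise rank-sum tests whose
    p-values are BH-adjusted jointly across all pairs tested.  Features with
    fewer than ``min_records`` records in fewer than two classes are skipped
    (logged).

    Returns ``(omnibus, pairwise)`` DataFrames.
    """
    if table.records is None or not len(table.records):
        return (
            pd.DataFrame(columns=["feature", "statistic", "p", "p_adj"]),
            pd.DataFrame(columns=["feature", "class_a", "class_b", "statistic", "p", "p_adj"]),
        )
    omnibus_rows = []
    groups_by_feature: dict[str, dict] = {}
    for feat, sub in table.records.groupby("feature"):
        groups = {
            c: g["value"].to_numpy()
            for c, g in sub.groupby("class")
            if len(g) >= min_records
        }
        if len(groups) < 2:
            logger.info("feature %s skipped: fewer than 2 classes with records", feat)
            continue
        samples = list(groups.values())
        if all(np.all(s == samples[0][0]) for s in samples):
            stat, p = 0.0, 1.0  # identical constant groups carry no signal
        else:
            stat, p = stats.kruskal(*samples)
        groups_by_feature[feat] = groups
        omnibus_rows.append((feat, float(stat), float(p)))
    omnibus = pd.DataFrame(omnibus_rows, columns=["feature", "statistic", "p"])
    if len(omnibus):
        omnibus["p_adj"] = multipletests(omnibus["p"], method="fdr_bh")[1]
    else:
        omnibus["p_adj"] = []

    pair_rows = []
    for _, r in omnibus[omnibus["p_adj"] <= alpha].iterrows():
        groups = groups_by_feature[r["feature"]]
        for a, b in combinations(sorted(groups, key=str), 2):
            ga, gb = groups[a], groups[b]
            if np.all(ga == ga[0]) and np.all(gb == gb[0]) and ga[0] == gb[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
            pair_rows.append((r["feature"], a, b, float(stat), float(p)))
    pairwise = pd.DataFrame(
        pair_rows, columns=["feature", "class_a", "class_b", "statistic", "p"]
    )
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = []
    return omnibus, pairwise
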