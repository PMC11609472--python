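"""Experiment orchestration: splits, metrics, and the end-to-end pipeline.

The evaluation protocol holds 30 % of samples out for testing and splits
the remaining 70 % into training and validation 80:20, with per-class
proportional allocation (largest-remainder rounding) so class frequencies
stay balanced across subsets.  Reported metrics are accuracy and weighted
precision/recall/F1 (macro F1 alongside), as percentages, with mean ± sd
over repeated seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boost import fit_boosted_ensemble, predict_boosted
from .clifi import collect_clifi
from .datasets import (
    default_planted_spec,
    frame_to_dataset,
    iris_with_noise,
    permute_within_columns,
    synthetic_planted,
)
from .forest import fit_bagged_ensemble, predict_majority, proximity_matrix
from .network import FeatureDistanceMatrix, neighbourhoods
from .tree import LabeledDataset, TreeParams

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "stratified_three_way_split",
    "classification_report",
    "fit_and_score",
    "run_pipeline",
    "grid_search",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Three-way split fractions: test share, then val share of the rest."""

    test_fraction: float = 0.30
    val_fraction_of_remainder: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if not (0 < self.val_fraction_of_remainder < 1):
            raise ValueError("val_fraction_of_remainder must be in (0, 1)")


@dataclass
class MetricsReport:
    """Percent-scale classification metrics (as printed in results tables)."""

    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    f1_macro: float
    per_class_f1: dict = field(default_factory=dict)
    n_runs: int = 1

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "f1_macro": self.f1_macro,
        }


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``targets``."""
    floors = np.floor(targets).astype(int)
    leftover = total - floors.sum()
    fracs = targets - floors
    # assign leftover units to the largest fractional parts; ties favour the
    # later subset in (test, val, train) order, i.e. train first
    order = np.argsort(-(fracs + np.arange(len(targets)) * 1e-12))
    for i in range(leftover):
        floors[order[i]] += 1
    return floors


def stratified_three_way_split(
    dataset: LabeledDataset, plan: SplitPlan
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index sets, stratified by class.

    Within every class the three subset sizes are the largest-remainder
    rounding of (test_fraction, (1-test)·val_fraction, rest); classes with
    fewer than 3 samples raise an error naming the class.
    """
    rng = np.random.default_rng(plan.seed)
    train, val, test = [], [], []
    for c in dataset.classes():
        idx = np.flatnonzero(dataset.y == c)
        if idx.size < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
        n_c = idx.size
        t_test = n_c * plan.test_fraction
        t_val = (n_c - t_test) * plan.val_fraction_of_remainder
        t_train = n_c - t_test - t_val
        n_test, n_val, n_train = _largest_remainder(
            np.array([t_test, t_val, t_train]), n_c
        )
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        val.append(perm[n_test : n_test + n_val])
        train.append(perm[n_test + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray, class_list: list
) -> MetricsReport:
    """Accuracy plus support-weighted precision/recall/F1, in percent.

    A class never predicted contributes precision 0; weights are true-class
    supports.  Unknown labels raise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    known = set(class_list)
    for v in np.unique(np.concatenate([y_true, y_pred])):
        if v not in known:
            raise ValueError(f"unknown label {v!r}")
    K = len(class_list)
    pos = {c: k for k, c in enumerate(class_list)}
    conf = np.zeros((K, K))
    for t, p in zip(y_true, y_pred):
        conf[pos[t], pos[p]] += 1
    support = conf.sum(axis=1)
    predicted = conf.sum(axis=0)
    diag = np.diag(conf)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, diag / predicted, 0.0)
        recall = np.where(support > 0, diag / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    weights = support / support.sum()
    present = support > 0
    return MetricsReport(
        accuracy=100.0 * float(diag.sum() / conf.sum()),
        precision_weighted=100.0 * float((weights * precision).sum()),
        recall_weighted=100.0 * float((weights * recall).sum()),
        f1_weighted=100.0 * float((weights * f1).sum()),
        f1_macro=100.0 * float(f1[present].mean()),
        per_class_f1={c: 100.0 * float(f1[pos[c]]) for c in class_list},
    )


# ---------------------------------------------------------------------------
# single fit + score
# ---------------------------------------------------------------------------

_ALGORITHMS = ("rf", "lavaset", "gbdt", "lavaboost")


def fit_and_score(
    dataset: LabeledDataset,
    algorithm: str,
    seed: int,
    *,
    n_trees: int = 150,
    n_rounds: int = 130,
    learning_rate: float = 0.1,
    max_features: str | int = "sqrt",
    sample_fraction: float = 0.8,
    neighbourhood_index=None,
    plan: SplitPlan | None = None,
):
    """Split, fit one model, and score the validation and test sets.

    Returns ``(model, report_val, report_test, splits)``.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm in ("lavaset", "lavaboost") and neighbourhood_index is None:
        raise ValueError(f"{algorithm} requires a neighbourhood index")
    plan = plan or SplitPlan(seed=seed)
    train_ix, val_ix, test_ix = stratified_three_way_split(dataset, plan)
    train = LabeledDataset(
        dataset.X[train_ix],
        dataset.y[train_ix],
        feature_names=list(dataset.feature_names),
        sample_ids=[dataset.sample_ids[i] for i in train_ix],
    )
    params = TreeParams(mode="classification", max_features=max_features, rng_seed=seed)
    neigh = neighbourhood_index if algorithm in ("lavaset", "lavaboost") else None
    if algorithm in ("rf", "lavaset"):
        model = fit_bagged_ensemble(
            train, params, n_trees=n_trees, sample_fraction=sample_fraction,
            neighbourhoods=neigh, seed=seed,
        )
        predict = lambda X: predict_majority(model, X)[0]
    else:
        model = fit_boosted_ensemble(
            train, params, n_rounds=n_rounds, learning_rate=learning_rate,
            neighbourhoods=neigh, seed=seed,
        )
        predict = lambda X: predict_boosted(model, X)[0]
    class_list = dataset.classes()
    rep_val = classification_report(dataset.y[val_ix], predict(dataset.X[val_ix]), class_list)
    rep_test = classification_report(dataset.y[test_ix], predict(dataset.X[test_ix]), class_list)
    return model, rep_val, rep_test, (train_ix, val_ix, test_ix)


def grid_search(
    dataset: LabeledDataset,
    algorithm: str,
    seed: int = 0,
    *,
    trees_grid=tuple(range(100, 190, 10)),
    rounds_grid=tuple(range(10, 160, 10)),
    lr_grid=(0.1, 0.2, 0.3),
    **kwargs,
) -> dict:
    """Plain grid over the model-size/learning-rate lists.

    Selection is on validation weighted F1; ties go to the smaller model
    (fewer trees or rounds, then smaller learning rate).
    """
    best = None
    if algorithm in ("rf", "lavaset"):
        for n_trees in trees_grid:
            _, rep, _, _ = fit_and_score(
                dataset, algorithm, seed, n_trees=n_trees, **kwargs
            )
            cand = {"n_trees": n_trees, "f1_weighted": rep.f1_weighted}
            if best is None or rep.f1_weighted > best["f1_weighted"]:
                best = cand
    else:
        for lr in lr_grid:
            for n_rounds in rounds_grid:
                _, rep, _, _ = fit_and_score(
                    dataset, algorithm, seed,
                    n_rounds=n_rounds, learning_rate=lr, **kwargs
                )
                cand = {
                    "n_rounds": n_rounds,
                    "learning_rate": lr,
                    "f1_weighted": rep.f1_weighted,
                }
                if best is None or rep.f1_weighted > best["f1_weighted"]:
                    best = cand
    return best


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "dataset", "label_column", "algorithm", "n_trees", "n_rounds",
    "learning_rate", "max_features", "sample_fraction", "theta",
    "distance_matrix", "seeds", "n_seeds", "base_seed", "outdir",
    "test_fraction", "val_fraction", "dataset_seed", "export_clifi",
    "export_proximity",
}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        cfg = dict(config)
    else:
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValueError("config must be a flat key-value file")
    unknown = sorted(set(cfg) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if "dataset" not in cfg or "algorithm" not in cfg:
        raise ValueError("config must name a dataset and an algorithm")
    return cfg


def _resolve_dataset(cfg: dict) -> LabeledDataset:
    name = cfg["dataset"]
    seed = int(cfg.get("dataset_seed", 0))
    if name == "iris_with_noise":
        return iris_with_noise(seed)
    if name == "iris_permuted":
        return permute_within_columns(iris_with_noise(seed), seed)
    if name == "synthetic_planted":
        ds, _, _ = synthetic_planted(default_planted_spec(seed))
        return ds
    df = pd.read_csv(name, index_col=0)
    return frame_to_dataset(df, cfg.get("label_column", "label"))


def run_pipeline(config) -> dict:
    """Fit the configured algorithm over a seed list and write artifacts.

    Writes ``metrics.csv`` (one row per seed plus mean/sd summary rows),
    ``clifi_records.csv``, ``aclifi.csv``/``naclifi.csv``, and
    ``proximity.csv`` (bagged models, training samples of the last seed)
    under ``outdir``.  Returns the paths written.
    """
    cfg = _load_config(config)
    outdir = Path(cfg.get("outdir", "clifitree_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = _resolve_dataset(cfg)
    algorithm = cfg["algorithm"]
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    seeds = cfg.get("seeds")
    if seeds is None:
        base = int(cfg.get("base_seed", 0))
        seeds = [base + i for i in range(int(cfg.get("n_seeds", 5)))]
    neigh = None
    if algorithm in ("lavaset", "lavaboost"):
        if "distance_matrix" not in cfg or "theta" not in cfg:
            raise ValueError(f"{algorithm} requires distance_matrix and theta")
        dist = FeatureDistanceMatrix.from_csv(cfg["distance_matrix"])
        if dist.feature_names != dataset.feature_names:
            raise ValueError("distance matrix features do not match the dataset")
        neigh = neighbourhoods(dist, float(cfg["theta"]))
    plan_kw = {}
    if "test_fraction" in cfg:
        plan_kw["test_fraction"] = float(cfg["test_fraction"])
    if "val_fraction" in cfg:
        plan_kw["val_fraction_of_remainder"] = float(cfg["val_fraction"])

    fit_kw = dict(
        n_trees=int(cfg.get("n_trees", 150)),
        n_rounds=int(cfg.get("n_rounds", 130)),
        learning_rate=float(cfg.get("learning_rate", 0.1)),
        max_features=cfg.get("max_features", "sqrt"),
        sample_fraction=float(cfg.get("sample_fraction", 0.8)),
        neighbourhood_index=neigh,
    )

    rows = []
    last_model = None
    last_train_ix = None
    for seed in seeds:
        plan = SplitPlan(seed=int(seed), **plan_kw)
        model, rep_val, rep_test, splits = fit_and_score(
            dataset, algorithm, int(seed), plan=plan, **fit_kw
        )
        last_model, last_train_ix = model, splits[0]
        row = {"seed": int(seed), "subset": "validation", **rep_val.as_dict()}
        rows.append(row)
        rows.append({"seed": int(seed), "subset": "test", **rep_test.as_dict()})
        logger.info("seed %s: val F1w %.2f%%, test F1w %.2f%%",
                    seed, rep_val.f1_weighted, rep_test.f1_weighted)
    metrics = pd.DataFrame(rows)
    summary = (
        metrics.groupby("subset")
        .agg(["mean", "std"])
        .drop(columns=["seed"])
    )
    paths = {"metrics": outdir / "metrics.csv", "summary": outdir / "metrics_summary.csv"}
    metrics.to_csv(paths["metrics"], index=False)
    summary.to_csv(paths["summary"])

    if cfg.get("export_clifi", True):
        table = collect_clifi(last_model, feature_names=dataset.feature_names)
        paths["clifi_records"] = outdir / "clifi_records.csv"
        table.records.to_csv(paths["clifi_records"], index=False)
        paths["aclifi"] = outdir / "aclifi.csv"
        paths["naclifi"] = outdir / "naclifi.csv"
        table.aclifi.to_csv(paths["aclifi"])
        table.naclifi.to_csv(paths["naclifi"])
    if cfg.get("export_proximity", True) and algorithm in ("rf", "lavaset"):
        prox = proximity_matrix(last_model, dataset.X[last_train_ix])
        ids = [dataset.sample_ids[i] for i in last_train_ix]
        paths["proximity"] = outdir / "proximity.csv"
        pd.DataFrame(prox, index=ids, columns=ids).to_csv(paths["proximity"])
    return {k: str(v) for k, v in paths.items()}
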