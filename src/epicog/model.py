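"""Ensemble diagnostic models under stratified five-fold cross-validation.

Two classifiers are supported: AdaBoost (SAMME.R) with probability-
calibrated RBF-SVC base learners, and gradient-boosted CART trees (GBDT).
Hyperparameters are chosen by exhaustive grid search with an inner
stratified five-fold on each training split (nested CV), maximizing mean
accuracy; the outer five folds yield per-fold accuracy, precision, recall,
F1 and ROC-AUC with the impaired (CI) group as the positive class.

The statsmodels-style entry point is :class:`CognitionClassifier`, whose
``fit()`` returns a :class:`CVResults` with a Table-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .boosting import SAMMERClassifier
from .selection import FisherRanking, fisher_score, select_top_k

__all__ = [
    "ALGORITHMS",
    "ModelConfig",
    "CVResults",
    "CognitionClassifier",
    "default_grid",
    "small_grid",
    "make_folds",
    "grid_search_fit",
    "cross_validate",
    "compute_metrics",
]

ALGORITHMS = ("adaboost_svm", "gbdt")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")

#: Full search grids (documented defaults; exhaustive and slow).
_FULL_GRIDS: dict[str, dict[str, list]] = {
    "adaboost_svm": {
        "n_estimators": [50, 75, 100, 125, 150],
        "learning_rate": [round(0.1 * i, 1) for i in range(1, 11)],
        "estimator__C": [float(2**e) for e in range(-10, 11, 2)],
        "estimator__gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0],
    },
    "gbdt": {
        "n_estimators": [50, 75, 100, 125, 150],
        "learning_rate": [round(0.1 * i, 1) for i in range(1, 11)],
        "subsample": [0.5, 0.6, 0.7, 0.8],
        "max_depth": [8, 10, 12, 15],
        "max_leaf_nodes": [10, 15, 20, 25, 30],
    },
}

#: Compact grids for quick runs; a small, representative corner of the full grid.
_SMALL_GRIDS: dict[str, dict[str, list]] = {
    "adaboost_svm": {
        "n_estimators": [50],
        "learning_rate": [0.3],
        "estimator__C": [1.0, 64.0],
        "estimator__gamma": [0.01, 0.25],
    },
    "gbdt": {
        "n_estimators": [100],
        "learning_rate": [0.1, 0.5],
        "subsample": [0.7],
        "max_depth": [8, 12],
        "max_leaf_nodes": [15],
    },
}


def default_grid(algorithm: str) -> dict[str, list]:
    return {k: list(v) for k, v in _FULL_GRIDS[algorithm].items()}


def small_grid(algorithm: str) -> dict[str, list]:
    return {k: list(v) for k, v in _SMALL_GRIDS[algorithm].items()}


@dataclass
class ModelConfig:
    """Algorithm choice plus its hyperparameter search space."""

    algorithm: str
    param_grid: dict[str, list] | None = None  # None -> full default grid
    fixed: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.param_grid is None:
            self.param_grid = default_grid(self.algorithm)
        if any(len(v) == 0 for v in self.param_grid.values()):
            raise ValueError("empty grid dimension")


def _base_estimator(cfg: ModelConfig):
    if cfg.algorithm == "adaboost_svm":
        svc = SVC(kernel="rbf", probability=True, random_state=cfg.seed)
        est = SAMMERClassifier(estimator=svc, random_state=cfg.seed)
    else:
        est = GradientBoostingClassifier(random_state=cfg.seed)
    if cfg.fixed:
        est.set_params(**cfg.fixed)
    return est


def make_folds(labels: pd.Series | np.ndarray, n_folds: int = 5, seed: int = 0):
    """Stratified partition into ``n_folds`` disjoint test folds.

    Returns a list of (train_idx, test_idx) positional index pairs; each
    class must contribute at least one subject per fold.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def grid_search_fit(X: np.ndarray, y: np.ndarray, cfg: ModelConfig):
    """Exhaustive grid search with inner stratified CV; refit on all data.

    Returns (fitted estimator, chosen parameter dict).
    """
    est = _base_estimator(cfg)
    grid_size = int(np.prod([len(v) for v in cfg.param_grid.values()]))
    if grid_size == 1:
        params = {k: v[0] for k, v in cfg.param_grid.items()}
        est.set_params(**params)
        est.fit(X, y)
        return est, params
    inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed)
    gs = GridSearchCV(est, cfg.param_grid, scoring="accuracy", cv=inner, n_jobs=1, refit=True)
    gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_)


def compute_metrics(y_true, y_pred, y_score) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and trapezoidal ROC-AUC (positive class 1 = CI).

    Undefined precision (no positive predictions) is reported as 0 with a
    ``precision_undefined`` flag.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValueError("length mismatch")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    out: dict[str, float] = {"accuracy": (tp + tn) / len(y_true)}
    out["precision_undefined"] = float(tp + fp == 0)
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    out["recall"] = tp / (tp + fn) if tp + fn else 0.0
    pr, rc = out["precision"], out["recall"]
    out["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    if len(np.unique(y_true)) == 2:
        out["auc"] = float(roc_auc_score(y_true, y_score))
    else:
        out["auc"] = float("nan")
    return out


def _positive_score(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, list(est.classes_).index(1)]
    return est.decision_function(X)


def cross_validate(
    table: pd.DataFrame, labels: pd.Series, cfg: ModelConfig, n_folds: int = 5
) -> "CVResults":
    """Outer stratified CV with nested grid search per fold; Table-style report."""
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    rows, chosen, roc_points = [], [], []
    for k, (tr, te) in enumerate(make_folds(y, n_folds=n_folds, seed=cfg.seed), start=1):
        est, params = grid_search_fit(X[tr], y[tr], cfg)
        y_pred = est.predict(X[te])
        y_score = _positive_score(est, X[te])
        m = compute_metrics(y[te], y_pred, y_score)
        m["fold"] = f"Fold {k}"
        rows.append(m)
        chosen.append(params)
        roc_points.append(pd.DataFrame({"fold": k, "y_true": y[te], "y_score": y_score}))
    per_fold = pd.DataFrame(rows).set_index("fold")[list(METRIC_NAMES)]
    return CVResults(
        algorithm=cfg.algorithm,
        per_fold=per_fold,
        chosen_hyperparameters=chosen,
        seed=cfg.seed,
        n_features=table.shape[1],
        roc_points=pd.concat(roc_points, ignore_index=True),
    )


@dataclass
class CVResults:
    """Cross-validation results: per-fold metrics, their mean, chosen settings."""

    algorithm: str
    per_fold: pd.DataFrame  # 5 rows x (accuracy, precision, recall, f1, auc)
    chosen_hyperparameters: list[dict[str, Any]]
    seed: int
    n_features: int
    roc_points: pd.DataFrame | None = None
    ranking: FisherRanking | None = None

    @property
    def mean_row(self) -> pd.Series:
        return self.per_fold.mean(axis=0).rename("Mean-value")

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.per_fold, self.mean_row.to_frame().T])

    def summary(self) -> str:
        lines = [
            f"Cognition classification — {self.algorithm}",
            f"features used: {self.n_features}   outer folds: {len(self.per_fold)}   seed: {self.seed}",
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "chosen hyperparameters per fold:",
        ]
        lines += [f"  Fold {i + 1}: {p}" for i, p in enumerate(self.chosen_hyperparameters)]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Write the metric table as CSV and settings as JSON alongside."""
        import json

        path = Path(path)
        self.to_frame().to_csv(path.with_suffix(".csv"))
        meta = {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "n_features": self.n_features,
            "mean": {k: float(v) for k, v in self.mean_row.items()},
            "chosen_hyperparameters": self.chosen_hyperparameters,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


class CognitionClassifier:
    """Diagnostic model for the CON/CI label built from a subject feature table.

    Wraps Fisher-score screening plus nested-CV ensemble classification.

    Parameters
    ----------
    table : DataFrame [subjects x features] — clinical, PLV or combined view
    labels : Series of 0 (CON) / 1 (CI) aligned to ``table``
    algorithm : 'adaboost_svm' or 'gbdt'
    top_k : number of Fisher-ranked features the classifier consumes
        (None = all columns)
    select_per_fold : if True, re-rank features inside every training fold
        (leakage-free); default False screens once on the full table, which
        mirrors the screening-before-modeling sequence but leaks ranking
        information across folds — see the methods note.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        labels: pd.Series,
        algorithm: str = "gbdt",
        top_k: int | None = None,
        param_grid: dict[str, list] | None = None,
        select_per_fold: bool = False,
        seed: int = 0,
    ):
        self.table = table
        self.labels = labels
        self.config = ModelConfig(algorithm=algorithm, param_grid=param_grid, seed=seed)
        self.top_k = top_k
        self.select_per_fold = select_per_fold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "group", **kw) -> "CognitionClassifier":
        labels = df[label_col]
        if labels.dtype == object:
            labels = labels.map({"CON": 0, "CI": 1})
        return cls(df.drop(columns=[label_col]), labels, **kw)

    def fit(self, n_folds: int = 5) -> CVResults:
        ranking = fisher_score(self.table, self.labels)
        if self.top_k is None or self.select_per_fold:
            table = self.table
        else:
            table = select_top_k(ranking, self.table, self.top_k)
        if self.select_per_fold and self.top_k is not None:
            res = self._fit_per_fold_selection(n_folds)
        else:
            res = cross_validate(table, self.labels, self.config, n_folds=n_folds)
        res.ranking = ranking
        return res

    def _fit_per_fold_selection(self, n_folds: int) -> CVResults:
        X_full = self.table
        y = np.asarray(self.labels)
        rows, chosen, roc_points = [], [], []
        for k, (tr, te) in enumerate(make_folds(y, n_folds=n_folds, seed=self.config.seed), 1):
            rank_tr = fisher_score(X_full.iloc[tr], self.labels.iloc[tr])
            cols = rank_tr.feature_names[: self.top_k]
            X = X_full[cols].to_numpy(dtype=float)
            est, params = grid_search_fit(X[tr], y[tr], self.config)
            y_pred = est.predict(X[te])
            y_score = _positive_score(est, X[te])
            m = compute_metrics(y[te], y_pred, y_score)
            m["fold"] = f"Fold {k}"
            rows.append(m)
            chosen.append(params)
            roc_points.append(pd.DataFrame({"fold": k, "y_true": y[te], "y_score": y_score}))
        per_fold = pd.DataFrame(rows).set_index("fold")[list(METRIC_NAMES)]
        return CVResults(
            algorithm=self.config.algorithm,
            per_fold=per_fold,
            chosen_hyperparameters=chosen,
            seed=self.config.seed,
            n_features=self.top_k,
            roc_points=pd.concat(roc_points, ignore_index=True),
        )
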