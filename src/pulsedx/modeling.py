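"""Robust scaling, grid-searched hyperparameters, and the eight classifiers.

Features are normalized as (x − median) / IQR with statistics fitted on
training rows only (IQR uses linear-interpolation quantiles; a zero IQR is
replaced by 1 and logged).  Hyperparameters are chosen by exhaustive grid
search under 5-fold cross-validation stratified by label and grouped by
patient, selecting on mean fold accuracy with ties broken toward the simpler
model.  Eight classifier families are supported: decision tree, random
forest, KNN, SVM, logistic regression, Gaussian naive Bayes, gradient
boosting, and LightGBM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

TECHNIQUES = (
    "decision_tree",
    "random_forest",
    "knn",
    "svm",
    "logistic_regression",
    "naive_bayes",
    "gradient_boosting",
    "lgbm",
)


class RobustScaler:
    """Median/IQR feature normalization with a fitted-row audit trail.

    transform(x) = (x − median) / IQR, with quantiles computed by linear
    interpolation.  Features with IQR 0 get divisor 1 and are recorded in
    ``zero_iqr_features``; the index of the rows the scaler was fitted on is
    kept in ``fitted_rows`` for leakage audits.
    """

    def __init__(self) -> None:
        self.median_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.feature_names_: list[str] | None = None
        self.zero_iqr_features: list[str] = []
        self.fitted_rows: list = []

    def fit(self, X: pd.DataFrame) -> "RobustScaler":
        if len(X) == 0:
            raise ValueError("cannot fit a scaler on an empty training set")
        values = X.to_numpy(dtype=float)
        self.median_ = np.median(values, axis=0)
        q75 = np.percentile(values, 75, axis=0, method="linear")
        q25 = np.percentile(values, 25, axis=0, method="linear")
        iqr = q75 - q25
        self.feature_names_ = list(X.columns)
        self.zero_iqr_features = [
            self.feature_names_[i] for i in np.nonzero(iqr == 0)[0]
        ]
        self.scale_ = np.where(iqr == 0, 1.0, iqr)
        self.fitted_rows = list(X.index)
        return self

    def _check(self, X: pd.DataFrame) -> None:
        if self.median_ is None:
            raise ValueError("scaler is not fitted")
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature columns differ from those the scaler was fitted on")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        return (X - self.median_) / self.scale_

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        return X * self.scale_ + self.median_


def default_grid(technique: str) -> list[dict[str, Any]]:
    """Modest per-technique hyperparameter grids (the study reports none)."""
    grids = {
        "decision_tree": {"max_depth": [2, 4, 8, None]},
        "random_forest": {"n_estimators": [100, 300]},
        "knn": {"n_neighbors": [3, 5, 9]},
        "svm": {"kernel": ["linear", "rbf"], "C": [0.1, 1.0, 10.0]},
        "logistic_regression": {"C": [0.1, 1.0, 10.0]},
        "naive_bayes": {},
        "gradient_boosting": {"n_estimators": [100, 300]},
        "lgbm": {"n_estimators": [100, 300]},
    }
    if technique not in grids:
        raise ValueError(f"unknown technique {technique!r}")
    return list(ParameterGrid(grids[technique]))


def make_estimator(technique: str, params: dict[str, Any], seed: int = 0):
    params = dict(params)
    if technique == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if technique == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if technique == "knn":
        return KNeighborsClassifier(**params)
    if technique == "svm":
        return SVC(random_state=seed, **params)
    if technique == "logistic_regression":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if technique == "naive_bayes":
        return GaussianNB(**params)
    if technique == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if technique == "lgbm":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, min_child_samples=5, **params
        )
    raise ValueError(f"unknown technique {technique!r}")


def _complexity_key(technique: str, params: dict[str, Any]) -> tuple:
    """Tie-break order: fewest estimators, smallest depth, fewest neighbors,
    strongest regularization (smallest C), linear before RBF."""
    if technique in ("random_forest", "gradient_boosting", "lgbm"):
        return (params.get("n_estimators", 0),)
    if technique == "decision_tree":
        depth = params.get("max_depth")
        return (np.inf if depth is None else depth,)
    if technique == "knn":
        return (params.get("n_neighbors", 0),)
    if technique == "svm":
        return (params.get("C", 1.0), 0 if params.get("kernel") == "linear" else 1)
    if technique == "logistic_regression":
        return (params.get("C", 1.0),)
    return (0,)


@dataclass
class ModelSpec:
    technique: str
    grid: list[dict[str, Any]] = field(default_factory=list)
    chosen: dict[str, Any] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if not self.grid:
            self.grid = default_grid(self.technique)


def _canonical_order(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Row order independent of input order (groups, label, then features)."""
    keys = [X[c].to_numpy() for c in reversed(X.columns.tolist())]
    keys.append(y)
    keys.append(pd.factorize(groups, sort=True)[0])
    return np.lexsort(keys)


def grid_search(
    units_frame_X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    spec: ModelSpec,
    k: int = 5,
    seed: int | None = None,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Exhaustive grid search with label-stratified, patient-grouped k-folds.

    The scaler is refitted on each fold's training rows.  Selection is by
    mean fold accuracy; ties break toward the simpler model.  Rows are
    canonically reordered first so the result is invariant to input order.
    """
    if not spec.grid:
        raise ValueError("hyperparameter grid is empty")
    y = np.asarray(y)
    groups = np.asarray(groups)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    seed = spec.seed if seed is None else seed

    order = _canonical_order(units_frame_X, y, groups)
    X = units_frame_X.iloc[order]
    y = y[order]
    groups = groups[order]

    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y, groups))
    for _, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a cross-validation fold contains a single class")

    rows = []
    for params in spec.grid:
        accs = []
        for tr, te in folds:
            scaler = RobustScaler().fit(X.iloc[tr])
            model = make_estimator(spec.technique, params, seed=seed)
            model.fit(scaler.transform(X.iloc[tr]), y[tr])
            pred = model.predict(scaler.transform(X.iloc[te]))
            accs.append(float((pred == y[te]).mean()))
        rows.append({"params": params, "fold_accuracies": accs, "mean_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best_acc = table["mean_accuracy"].max()
    candidates = [r for r in rows if r["mean_accuracy"] == best_acc]
    chosen = min(candidates, key=lambda r: _complexity_key(spec.technique, r["params"]))
    return dict(chosen["params"]), table


def fit_scaler(X: pd.DataFrame) -> RobustScaler:
    """Median/IQR scaler fitted on training units only."""
    if len(X) < 2:
        raise ValueError("need at least 2 training units to fit the scaler")
    return RobustScaler().fit(X)


@dataclass
class TrainedModel:
    spec: ModelSpec
    scaler: RobustScaler
    estimator: Any
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError("unit width/columns do not match the trained model")
        return self.estimator.predict(self.scaler.transform(X)).astype(int)


def train(
    X: pd.DataFrame, y: np.ndarray, spec: ModelSpec, scaler: RobustScaler
) -> TrainedModel:
    """Fit the chosen technique on scaled training units."""
    if scaler.median_ is None:
        raise ValueError("scaler must be fitted before training")
    if list(X.index) != list(scaler.fitted_rows):
        raise ValueError("scaler was fitted on different training rows")
    params = spec.chosen if spec.chosen is not None else spec.grid[0]
    estimator = make_estimator(spec.technique, params, seed=spec.seed)
    estimator.fit(scaler.transform(X), np.asarray(y))
    return TrainedModel(spec=spec, scaler=scaler, estimator=estimator, feature_names=list(X.columns))
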