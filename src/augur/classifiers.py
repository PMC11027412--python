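"""Classifier backends behind a single train/predict contract.

Five algorithms are supported: random forest (the final predictor:
160 trees, Gini criterion, sqrt max-features), LightGBM (31 leaves,
learning rate 0.1), L2 logistic regression (L-BFGS), polynomial-kernel
SVM (cross-validated Platt sigmoid for probabilities), and KNN (K = 3).
Distance-based backends (knn, svm) and the logistic regression consume
z-scored features; tree ensembles consume raw values. Every trained
model is a self-contained bundle: feature names, scaler, fitted state.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ALGORITHMS = ("rf", "lgbm", "lr", "svm", "knn")
#: Backends that consume standardized features.
SCALED_ALGORITHMS = frozenset({"lr", "svm", "knn"})

#: Default hyperparameters per backend (tuning outcomes of the protocol).
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "rf": {"n_estimators": 160, "criterion": "gini", "max_features": "sqrt"},
    "lgbm": {"num_leaves": 31, "learning_rate": 0.1, "n_estimators": 100},
    "lr": {"solver": "lbfgs", "max_iter": 2000},  # L2 penalty (the default)
    "svm": {"kernel": "poly", "degree": 3, "C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 3},
}

#: Default tuning grids, within the protocol's stated ranges
#: (trees 5-300; leaves 20-100; learning rate 0.01-0.15; C 0.1-15;
#: gamma 0.001-10).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [5, 20, 40, 80, 160, 300]},
    "lgbm": {
        "num_leaves": [20, 31, 60, 100],
        "learning_rate": [0.01, 0.05, 0.1, 0.15],
    },
    "lr": {"C": [0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 15.0], "gamma": [0.001, 0.1, 10.0]},
    "knn": {"n_neighbors": [3, 5, 7]},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice + hyperparameters + tuning grid."""

    algorithm: str = "rf"
    params: Mapping[str, Any] = field(default_factory=dict)
    grid: Mapping[str, list] | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    @property
    def resolved_params(self) -> dict[str, Any]:
        return {**DEFAULT_PARAMS[self.algorithm], **dict(self.params)}

    def with_params(self, **params: Any) -> "ModelSpec":
        return replace(self, params={**dict(self.params), **params})


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn / LightGBM estimator for a spec."""
    p = spec.resolved_params
    if spec.algorithm == "rf":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=spec.seed, verbose=-1, **p)
    if spec.algorithm == "lr":
        return LogisticRegression(random_state=spec.seed, **p)
    if spec.algorithm == "svm":
        from sklearn.calibration import CalibratedClassifierCV

        # cross-validated Platt sigmoid supplies probability scores
        return CalibratedClassifierCV(
            SVC(random_state=spec.seed, **p), method="sigmoid", cv=5
        )
    return KNeighborsClassifier(**p)


@dataclass
class TrainedModel:
    """A fitted backend plus everything needed for standalone prediction."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    scaler: StandardScaler | None = None
    descriptor_config: Any = None  # DescriptorConfig when trained from sequences
    selection_thresholds: pd.Series | None = None

    def _prepare(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in matrix.columns]
        if missing:
            raise ValueError(
                f"input is missing {len(missing)} required feature(s), "
                f"e.g. {missing[:5]}"
            )
        X = matrix.loc[:, self.feature_names]
        if self.scaler is not None:
            return self.scaler.transform(X.to_numpy(dtype=float))
        return X  # keep the frame so estimators see consistent feature names

    def predict_scores(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per-row positive-class score in [0, 1] and the class at a 0.5
        threshold; columns are aligned by name, never position."""
        X = self._prepare(matrix)
        scores = self.estimator.predict_proba(X)[:, 1]
        return pd.DataFrame(
            {"score": scores, "predicted": (scores >= 0.5).astype(int)},
            index=matrix.index,
        )

    def save(self, path: str | Path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with Path(path).open("rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel bundle")
        return model


def train_classifier(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    descriptor_config: Any = None,
    selection_thresholds: pd.Series | None = None,
) -> TrainedModel:
    """Fit one backend; seed-deterministic, single-class and non-finite
    inputs rejected."""
    if spec is None:
        spec = ModelSpec()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("training matrix contains non-finite values")
    scaler = None
    if spec.algorithm in SCALED_ALGORITHMS:
        scaler = StandardScaler().fit(matrix.to_numpy(dtype=float))
        X = scaler.transform(matrix.to_numpy(dtype=float))
    else:
        X = matrix
    estimator = build_estimator(spec).fit(X, labels)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=list(matrix.columns),
        scaler=scaler,
        descriptor_config=descriptor_config,
        selection_thresholds=selection_thresholds,
    )


def _grid_points(grid: Mapping[str, list]) -> list[dict[str, Any]]:
    from itertools import product

    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _complexity_key(algorithm: str, params: dict[str, Any]) -> tuple:
    """Tie-break ordering: simpler models first (fewer trees/leaves,
    smaller C/K, smaller learning rate)."""
    order = {
        "rf": ("n_estimators",),
        "lgbm": ("num_leaves", "learning_rate"),
        "lr": ("C",),
        "svm": ("C", "gamma"),
        "knn": ("n_neighbors",),
    }[algorithm]
    return tuple(params.get(k, 0) for k in order)


def grid_search(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Exhaustive 5-fold cross-validated AUROC over the tuning grid.

    Returns (best parameters, table of per-point mean scores); ties go
    to the simpler parameter combination. Infeasible points are skipped
    with a warning.
    """
    if spec is None:
        spec = ModelSpec()
    labels = np.asarray(labels)
    grid = dict(spec.grid) if spec.grid is not None else DEFAULT_GRIDS[spec.algorithm]
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty tuning grid")
    X = matrix.to_numpy(dtype=float)
    if spec.algorithm in SCALED_ALGORITHMS:
        X = StandardScaler().fit_transform(X)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    rows = []
    for params in points:
        try:
            est = build_estimator(spec.with_params(**params))
            score = cross_val_score(est, X, labels, cv=cv, scoring="roc_auc").mean()
        except Exception as exc:  # noqa: BLE001 - infeasible grid point
            warnings.warn(f"grid point {params} skipped: {exc}", stacklevel=2)
            continue
        rows.append({**params, "cv_auroc": float(score)})
    if not rows:
        raise ValueError("every grid point failed")
    table = pd.DataFrame(rows)
    best_score = table["cv_auroc"].max()
    tied = table[table["cv_auroc"] >= best_score - 1e-12]
    tied_params = [
        {k: row[k] for k in grid} for _, row in tied.iterrows()
    ]
    best = min(tied_params, key=lambda p: _complexity_key(spec.algorithm, p))
    return best, table
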