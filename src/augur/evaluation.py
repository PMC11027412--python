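"""Model evaluation: confusion-matrix metrics, AUROC, and leakage-safe
five-fold cross-validation.

Metrics follow the standard definitions: Sn = TP/(TP+FN),
Sp = TN/(TN+FP), ACC = (TP+TN)/N,
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) (0 when any
denominator factor vanishes), F1 = 2 Sn Pre / (Sn + Pre) with
Pre = TP/(TP+FP). AUROC uses the rank (Mann-Whitney) convention with
tied scores contributing one half.

Inside cross-validation every data-dependent step — standardization,
augmentation, feature binarization, information-gain selection, model
fitting — is fit on the training portion of each fold only, so no
synthetic sample and no statistic of the validation rows ever leaks
into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .augmentation import AugmentationPlan, augment_training_set
from .classifiers import ModelSpec, train_classifier
from .feature_selection import (
    DEFAULT_SCAN_GRID,
    binarize_features,
    rank_features,
    select_topk,
)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP at a fixed decision threshold."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @staticmethod
    def from_predictions(
        labels: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(int)
        predicted = np.asarray(predicted).astype(int)
        return ConfusionCounts(
            tp=int(((labels == 1) & (predicted == 1)).sum()),
            fn=int(((labels == 1) & (predicted == 0)).sum()),
            tn=int(((labels == 0) & (predicted == 0)).sum()),
            fp=int(((labels == 0) & (predicted == 1)).sum()),
        )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, ACC, MCC, F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("need at least one positive and one negative")
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    pre = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    f1 = 0.0 if sn + pre == 0 else 2 * sn * pre / (sn + pre)
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": float(mcc), "F1": f1}


def roc_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Rank-based AUROC plus the threshold-sweep ROC curve points."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


@dataclass
class SelectionSettings:
    """How many top-IG features to keep inside each training fit.

    ``n_features`` fixes k directly (default 400, the coarse-scan
    plateau point); setting ``scan=True`` instead runs the 50..600
    coarse grid with an inner cross-validated evaluator, optionally
    refined by ternary search (``ternary=True``).
    """

    n_features: int = 400
    scan: bool = False
    ternary: bool = False
    scan_grid: Sequence[int] = DEFAULT_SCAN_GRID
    inner_folds: int = 3


@dataclass
class EvaluationReport:
    """Per-fold and aggregated metrics."""

    fold_metrics: list[dict[str, float]]
    fold_confusions: list[ConfusionCounts]
    roc_points: list[pd.DataFrame] = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict[str, float]:
        keys = self.fold_metrics[0].keys()
        return {
            k: float(np.mean([m[k] for m in self.fold_metrics])) for k in keys
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fold_metrics)
        df.index = [f"fold_{i + 1}" for i in range(len(df))]
        df.loc["mean"] = df.mean()
        return df

    def to_dict(self) -> dict:
        return {
            "folds": self.fold_metrics,
            "mean": self.mean_metrics,
            "confusions": [vars(c) for c in self.fold_confusions],
        }


def _fit_fold(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    plan: Optional[AugmentationPlan],
    selection: SelectionSettings,
    spec: ModelSpec,
    seed: int,
):
    """One leakage-safe training fit: augment, select, train."""
    if plan is not None:
        fold_plan = plan.scaled_to(int(train_y.sum()), seed=seed)
        train_X, train_y, _ = augment_training_set(train_X, train_y, fold_plan)
    binary, thresholds = binarize_features(train_X)
    ranking = rank_features(train_X, train_y, thresholds)
    if selection.scan or selection.ternary:
        def evaluator(features: Sequence[str]) -> float:
            inner = StratifiedKFold(
                n_splits=selection.inner_folds, shuffle=True, random_state=seed
            )
            aucs = []
            X, y = train_X.loc[:, list(features)], train_y
            for tr, va in inner.split(X, y):
                model = train_classifier(X.iloc[tr], y[tr], spec)
                sc = model.predict_scores(X.iloc[va])["score"]
                aucs.append(roc_auc(y[va], sc)[0])
            return float(np.mean(aucs))

        grid = [k for k in selection.scan_grid if k <= train_X.shape[1]]
        k, _ = select_topk(ranking, evaluator, grid, refine=selection.ternary)
    else:
        k = min(selection.n_features, train_X.shape[1])
    features = ranking.top(k)
    model = train_classifier(
        train_X.loc[:, features], train_y, spec, selection_thresholds=thresholds
    )
    return model


def cross_validate(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    plan: Optional[AugmentationPlan] = None,
    selection: SelectionSettings | None = None,
    folds: int = 5,
    seed: int = 0,
    keep_roc: bool = True,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full training recipe.

    Augmentation (when a plan is given), feature binarization,
    information-gain selection, and model fitting all happen inside each
    training fold; the validation fold contains only untouched original
    rows.
    """
    if spec is None:
        spec = ModelSpec(seed=seed)
    if selection is None:
        selection = SelectionSettings()
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics, fold_conf, rocs = [], [], []
    for f, (tr, va) in enumerate(skf.split(matrix, labels)):
        model = _fit_fold(
            matrix.iloc[tr], labels[tr], plan, selection, spec, seed + f
        )
        preds = model.predict_scores(matrix.iloc[va])
        conf = ConfusionCounts.from_predictions(labels[va], preds["predicted"])
        metrics = compute_metrics(conf)
        auc, curve = roc_auc(labels[va], preds["score"].to_numpy())
        metrics["AUROC"] = auc
        fold_metrics.append(metrics)
        fold_conf.append(conf)
        if keep_roc:
            rocs.append(curve)
    return EvaluationReport(fold_metrics, fold_conf, rocs)


def evaluate_holdout(
    model, matrix: pd.DataFrame, labels: np.ndarray
) -> EvaluationReport:
    """Independent-set evaluation of a trained model."""
    preds = model.predict_scores(matrix)
    labels = np.asarray(labels)
    conf = ConfusionCounts.from_predictions(labels, preds["predicted"])
    metrics = compute_metrics(conf)
    auc, curve = roc_auc(labels, preds["score"].to_numpy())
    metrics["AUROC"] = auc
    return EvaluationReport([metrics], [conf], [curve])
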