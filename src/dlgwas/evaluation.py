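"""Splitting, cross-validation, and classification metrics.

The study protocol: a stratified 9:1 train/test split of the subjects, a
further 25% of the training portion held out for validation, stratified
5-fold cross-validation over the training pool, and per-fold accuracy,
sensitivity and specificity

    accuracy   = (Tn + Tp) / (Tn + Tp + Fn + Fp)
    sensitivity =  Tp / (Tp + Fn)
    specificity =  Tn / (Tn + Fp)

reported as mean +/- SD, with a pooled ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError


@dataclass
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def train_pool(self) -> np.ndarray:
        """Training + validation subjects (the 9/10 'training group')."""
        return np.sort(np.concatenate([self.train, self.validation]))


def split_dataset(
    labels, test_fraction: float = 0.1, validation_fraction: float = 0.25, seed: int = 0
) -> SplitIndices:
    """Stratified train/validation/test partition of sample indices.

    Per class: round(test_fraction * n) samples go to test, then
    floor(validation_fraction * remaining) to validation; partitions are
    disjoint, exhaustive, and reproducible from ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for c in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == c))
        if len(members) < 3:
            raise ConfigurationError(f"class {c!r} has fewer than 3 members")
        n_test = int(round(test_fraction * len(members)))
        te.extend(members[:n_test])
        rest = members[n_test:]
        n_val = int(np.floor(validation_fraction * len(rest)))
        va.extend(rest[:n_val])
        tr.extend(rest[n_val:])
    return SplitIndices(
        train=np.sort(np.array(tr, dtype=int)),
        validation=np.sort(np.array(va, dtype=int)),
        test=np.sort(np.array(te, dtype=int)),
    )


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is zero."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep) and trapezoidal AUC; labels in {0,1}."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = skmetrics.roc_curve(labels, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


@dataclass
class EvaluationResult:
    """Per-fold confusion counts and metrics plus pooled ROC."""

    folds: pd.DataFrame  # fold, tp, tn, fp, fn, accuracy, sensitivity, specificity
    roc: pd.DataFrame = None
    auc: float = float("nan")
    extra: dict = field(default_factory=dict)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = self.folds[metric].to_numpy(dtype=float)
        sd = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.nanmean(vals)), sd

    def summary(self) -> dict:
        out = {}
        for m in ("accuracy", "sensitivity", "specificity"):
            mean, sd = self.mean_sd(m)
            out[f"{m}_mean"] = mean
            out[f"{m}_sd"] = sd
        out["auc"] = self.auc
        return out


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive) -> tuple[int, int, int, int]:
    tp = int(((y_pred == positive) & (y_true == positive)).sum())
    tn = int(((y_pred != positive) & (y_true != positive)).sum())
    fp = int(((y_pred == positive) & (y_true != positive)).sum())
    fn = int(((y_pred != positive) & (y_true == positive)).sum())
    return tp, tn, fp, fn


def crossvalidate(
    estimator,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    X_test=None,
    y_test=None,
    mode: str = "fold_models_on_test",
    positive_class=None,
) -> EvaluationResult:
    """Stratified k-fold cross-validation of a classifier.

    ``mode='fold_models_on_test'`` fits one model per fold on the fold's
    training portion and evaluates every fold model on the single held-out
    test set (requires ``X_test``/``y_test``); ``mode='fold_internal'``
    evaluates each fold model on its own held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ConfigurationError("every class needs at least k members")
    if mode == "fold_models_on_test" and X_test is None:
        raise ConfigurationError("fold_models_on_test mode needs X_test / y_test")
    positive = positive_class if positive_class is not None else classes[-1]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, pooled_scores, pooled_truth = [], [], []
    for fold, (tr, ho) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = clone(estimator)
        if hasattr(est, "random_state"):
            est.random_state = seed * 1000 + fold
        est.fit(X[tr], y[tr])
        if mode == "fold_models_on_test":
            Xe, ye = X_test, np.asarray(y_test)
        else:
            Xe, ye = X[ho], y[ho]
        pred = est.predict(Xe)
        tp, tn, fp, fn = _confusion(ye, pred, positive)
        acc, sens, spec = compute_metrics(tp, tn, fp, fn)
        rows.append(
            {
                "fold": fold,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
        if hasattr(est, "predict_proba"):
            pos_col = int(np.flatnonzero(est.classes_ == positive)[0])
            pooled_scores.extend(est.predict_proba(Xe)[:, pos_col])
        else:
            pooled_scores.extend(est.decision_function(Xe))
        pooled_truth.extend(ye == positive)
    roc, auc = roc_auc(np.array(pooled_scores), np.array(pooled_truth, dtype=int))
    return EvaluationResult(folds=pd.DataFrame(rows), roc=roc, auc=auc)
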