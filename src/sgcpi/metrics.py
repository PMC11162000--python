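"""Binary-classification metrics and repeated stratified cross-validation.

Six metrics are reported: accuracy, precision, recall, F1 (all at a 0.5
decision threshold by default) plus the threshold-free ROC AUC and AUPR.
AUPR is computed as step-wise average precision, not trapezoidal
interpolation, because trapezoids over-estimate the precision-recall
area. Zero-division cases (no positive predictions, no true positives)
return 0 with a warning — a realistic outcome under the ~1:81 class
imbalance the evaluation protocol is designed around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "METRIC_NAMES",
    "CVPlan",
    "MetricsReport",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "all_metrics",
    "repeated_stratified_cv",
]

METRIC_NAMES = ["accuracy", "precision", "recall", "f1", "auc", "aupr"]


def _check_lengths(y, scores):
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs scores {s.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, s


def confusion_metrics(y, scores, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, precision, recall, F1 at the given threshold.

    The hard label is ``score >= threshold``. When no positive
    predictions exist, precision (and hence F1) is 0 with a warning;
    when no true positives exist, recall is 0 with a warning.
    """
    y, s = _check_lengths(y, scores)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    acc = (tp + tn) / y.size
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision defined as 0", stacklevel=2)
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall defined as 0", stacklevel=2)
        rec = 0.0
    elif tp == 0:
        warnings.warn("no true positives; recall is 0", stacklevel=2)
        rec = 0.0
    else:
        rec = tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def roc_auc(y, scores) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney concordance probability: the chance a random
    positive outscores a random negative, with ties counted 1/2.
    """
    y, s = _check_lengths(y, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined: only one class present")
    return float(roc_auc_score(y, s))


def pr_auc(y, scores) -> float:
    """Area under the precision-recall curve as step-wise average precision."""
    y, s = _check_lengths(y, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPR undefined: only one class present")
    return float(average_precision_score(y, s))


def all_metrics(y, scores, threshold: float = 0.5) -> dict[str, float]:
    out = confusion_metrics(y, scores, threshold)
    out["auc"] = roc_auc(y, scores)
    out["aupr"] = pr_auc(y, scores)
    return out


@dataclass(frozen=True)
class CVPlan:
    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass
class MetricsReport:
    """Per-fold/repeat metric rows plus mean/sd aggregation."""

    rows: pd.DataFrame  # columns: repeat, fold, + METRIC_NAMES

    def aggregate(self) -> pd.DataFrame:
        agg = self.rows[METRIC_NAMES].agg(["mean", "std"])
        return agg

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict[str, dict[str, float]]:
        agg = self.aggregate()
        return {
            m: {"mean": float(agg.loc["mean", m]), "sd": float(agg.loc["std", m])}
            for m in METRIC_NAMES
        }


def repeated_stratified_cv(
    labels: np.ndarray,
    plan: CVPlan,
    fit_fn: Callable[[np.ndarray], object],
    eval_fn: Callable[[object, np.ndarray], dict[str, float]],
) -> MetricsReport:
    """Repeated stratified K-fold harness.

    ``fit_fn(train_idx)`` returns a fitted model; ``eval_fn(model,
    test_idx)`` returns a metric dict. Each repeat reshuffles with a
    derived seed; every sample lands in exactly one test fold per repeat
    and class proportions are preserved to within one sample per fold.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < plan.folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than {plan.folds} folds"
        )
    if not plan.stratified:
        raise ValueError("only stratified CV is supported (imbalance protocol)")
    rows = []
    idx = np.arange(y.size)
    for r in range(plan.repeats):
        skf = StratifiedKFold(
            n_splits=plan.folds, shuffle=True, random_state=plan.seed + r
        )
        for f, (tr, te) in enumerate(skf.split(idx, y)):
            model = fit_fn(tr)
            m = eval_fn(model, te)
            rows.append({"repeat": r, "fold": f, **m})
    return MetricsReport(rows=pd.DataFrame(rows))
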