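"""Quartile normal ranges per age-group x gender and rank-based scoring.

The normal range of an HRV parameter for a demographic group is summarized
by its quartiles Q1/Q2/Q3, computed with the median-of-halves rule: Q2 is
the median; Q1 and Q3 are the medians of the lower and upper halves, with
the median itself excluded from both halves when n is odd. (Numeric
libraries default to interpolation-based quantiles, which differ.)

A predicted range is scored against the reference quartiles of the group
actually measured: the quartiles split the value axis into four rank bins
(-inf, q1], (q1, q2], (q2, q3], (q3, +inf). For one measured value, TP is 1
if its bin is among the predicted bins; FP counts predicted bins that were
not measured; FN is 1 when the measured bin was not predicted; TN the bins
neither predicted nor measured — so tp+fp+fn+tn = 4 per sample and counts
aggregate by summation.

The module also houses the generic classification/regression metrics and a
stratified cross-validation harness for classifying glucose-regulation
ability (ND/GD/BD) from HRV features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort_stats import age_group


@dataclass(frozen=True)
class QuartileRange:
    """Quartiles (and mean) of one (age_group, gender, parameter) cell."""

    q1: float
    q2: float
    q3: float
    n: int
    mean: float | None = None
    age_group: str | None = None
    gender: str | None = None
    parameter: str | None = None

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartiles must satisfy q1 <= q2 <= q3")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def tpr(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpr(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        if self.tpr is None or self.ppv is None:
            return None
        return f1_from_rates(self.tpr, self.ppv)


@dataclass(frozen=True)
class RegressionMetrics:
    mse: float
    rmse: float
    mae: float


def _median(sorted_vals: np.ndarray) -> float:
    n = sorted_vals.size
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return float((sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0)


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Median-of-halves Q1/Q2/Q3 (odd-n median excluded from both halves)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 4:
        raise ValueError("quartiles need at least 4 values")
    mid = v.size // 2
    lower = v[:mid]
    upper = v[mid + 1:] if v.size % 2 else v[mid:]
    return _median(lower), _median(v), _median(upper)


def group_quartiles(
    cohort: pd.DataFrame,
    parameter: str,
    min_n: int = 4,
) -> list[QuartileRange]:
    """QuartileRange per (age_group, gender) cell of a per-subject table.

    ``cohort`` needs columns ``age``, ``gender`` and the parameter column;
    rows with absent values are dropped; undersized cells are omitted.
    """
    df = cohort.dropna(subset=[parameter]).copy()
    df["_age_group"] = df["age"].map(age_group)
    out = []
    for (ag, sex), sub in df.groupby(["_age_group", "gender"], sort=False):
        vals = sub[parameter].to_numpy(dtype=float)
        if vals.size < min_n:
            continue
        q1, q2, q3 = quartiles(vals)
        out.append(
            QuartileRange(
                q1=q1, q2=q2, q3=q3, n=vals.size, mean=float(vals.mean()),
                age_group=ag, gender=sex, parameter=parameter,
            )
        )
    order = {g: i for i, g in enumerate(
        ("<30", "30-40", "40-50", "50-60", "60-70", ">70"))}
    out.sort(key=lambda r: (order.get(r.age_group, 99), r.gender))
    return out


def rank_bin(value: float, reference: QuartileRange) -> int:
    """Rank bin of a value under reference quartiles (right-closed bins)."""
    if value <= reference.q1:
        return 0
    if value <= reference.q2:
        return 1
    if value <= reference.q3:
        return 2
    return 3


def predicted_bins(predicted: QuartileRange, reference: QuartileRange) -> set[int]:
    """Reference bins spanned by the predicted [q1, q3] range."""
    return set(range(rank_bin(predicted.q1, reference),
                     rank_bin(predicted.q3, reference) + 1))


def rank_counts(predicted: set[int], measured_bin: int, n_bins: int = 4) -> EvalCounts:
    """TP/FP/FN/TN over rank bins for a single measured value."""
    if not 0 <= measured_bin < n_bins:
        raise ValueError("measured bin out of range")
    if any(b < 0 or b >= n_bins for b in predicted):
        raise ValueError("predicted bin out of range")
    tp = 1 if measured_bin in predicted else 0
    fp = len(predicted) - tp
    fn = 1 - tp
    tn = n_bins - tp - fp - fn
    return EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def rank_eval(
    predicted: QuartileRange, measured_value: float, reference: QuartileRange
) -> EvalCounts:
    """Score one predicted quartile range against one measured value."""
    return rank_counts(
        predicted_bins(predicted, reference), rank_bin(measured_value, reference)
    )


def f1_from_rates(tpr: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    if not (0 <= tpr <= 1 and 0 <= ppv <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if tpr + ppv == 0:
        return 0.0
    return 2.0 * tpr * ppv / (tpr + ppv)


def classification_metrics(confusion: np.ndarray) -> dict:
    """Accuracy and per-class/macro recall, precision, F1 from a K x K
    confusion matrix with rows = true classes."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    recall = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
    precision = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * recall * precision / (recall + precision)
    f1 = np.where((recall + precision) > 0, f1, 0.0)
    f1 = np.where(np.isnan(recall) | np.isnan(precision), np.nan, f1)
    if np.isnan(recall).any() or np.isnan(precision).any():
        warnings.warn("class with zero row/column excluded from macro metrics")
    return {
        "accuracy": float(diag.sum() / total),
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "macro_recall": float(np.nanmean(recall)),
        "macro_precision": float(np.nanmean(precision)),
        "macro_f1": float(np.nanmean(f1)),
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the probability a random positive outscores a random negative
    (Mann-Whitney identity; ties count one half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    n_pos = int((y == 1).sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def multiclass_auc(
    score_matrix: np.ndarray, labels: Sequence, classes: Sequence
) -> float:
    """Macro one-vs-rest AUC from per-class score columns."""
    labels = np.asarray(labels)
    aucs = []
    for j, cls in enumerate(classes):
        y = (labels == cls).astype(int)
        if 0 < y.sum() < y.size:
            aucs.append(roc_auc(score_matrix[:, j], y))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> RegressionMetrics:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("need at least one pair")
    err = yhat - y
    mse = float(np.mean(err**2))
    return RegressionMetrics(mse=mse, rmse=float(np.sqrt(mse)),
                             mae=float(np.mean(np.abs(err))))


GLUCO_FEATURES = ("A_SDNN", "A_rMSSD", "C_SDNN", "C_rMSSD")


def gluco_classify(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 10,
    learner=None,
    random_state: int = 0,
) -> dict:
    """Stratified k-fold CV of a glucose-regulation (ND/GD/BD) classifier.

    Features are the four HRV measures A_SDNN, A_rMSSD, C_SDNN, C_rMSSD
    (any numeric columns are accepted). F1 (macro) is the headline metric
    because of the strong class imbalance. The learner is pluggable; the
    default is an extra-trees ensemble. Returns the pooled confusion
    matrix, pooled metrics and per-fold macro F1.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    min_count = min(int((y == c).sum()) for c in classes)
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds"
        )
        folds = max(2, min_count)
    if learner is None:
        learner = ExtraTreesClassifier(n_estimators=200, random_state=random_state)
    cls_index = {c: i for i, c in enumerate(classes)}
    pooled = np.zeros((classes.size, classes.size), dtype=int)
    fold_f1 = []
    aucs = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    for train, test in skf.split(X, y):
        model = clone(learner)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        cm = np.zeros_like(pooled)
        for t, p in zip(y[test], pred):
            cm[cls_index[t], cls_index[p]] += 1
        pooled += cm
        fold_f1.append(classification_metrics(cm)["macro_f1"])
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X[test])
            try:
                aucs.append(multiclass_auc(proba, y[test], model.classes_))
            except ValueError:
                pass
    out = classification_metrics(pooled)
    out.update(
        confusion=pooled,
        classes=list(classes),
        fold_macro_f1=fold_f1,
        mean_fold_macro_f1=float(np.mean(fold_f1)),
        auc=float(np.mean(aucs)) if aucs else None,
        folds=folds,
    )
    return out
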