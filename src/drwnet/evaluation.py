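"""Metrics, curves, and statistical robustness utilities.

Binary metrics follow the standard confusion-count formulas (precision,
sensitivity, accuracy, specificity, F1, Dice); multiclass grading is scored
one-vs-rest per class and aggregated macro (unweighted mean) and weighted
(support-weighted mean).  ROC/PR use trapezoidal AUC and step-interpolated
average precision.  Bootstrap confidence intervals are percentile intervals
over seeded resamples; paired comparisons use the paired t statistic across
cross-validation folds.

Zero-denominator convention: precision/sensitivity/specificity are defined
as 0 when their denominator is 0 (logged warning), so degenerate inputs do
not crash aggregate reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

N_CLASSES = 5

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "binary_metrics",
    "multiclass_report",
    "roc_pr_curves",
    "bootstrap_ci",
    "paired_t_test",
    "stagewise_sensitivity",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    precision: float
    sensitivity: float
    accuracy: float
    specificity: float
    f1: float
    dice: float
    aggregation: str = "binary"

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "f1": self.f1,
            "dice": self.dice,
            "aggregation": self.aggregation,
        }


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; defining metric as 0", name)
        return 0.0
    return num / den


def binary_metrics(counts: ConfusionCounts) -> MetricSet:
    """Evaluate the six confusion-count formulas exactly."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    accuracy = (tp + tn) / counts.total
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "f1")
    dice = _safe_div(2 * tp, 2 * tp + fp + fn, "dice")
    return MetricSet(precision, sensitivity, accuracy, specificity, f1, dice)


def _ovr_counts(y_true: np.ndarray, y_pred: np.ndarray, cls: int) -> ConfusionCounts:
    t = y_true == cls
    p = y_pred == cls
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def multiclass_report(y_true, y_pred, n_classes: int = N_CLASSES) -> dict:
    """Confusion matrix plus macro and support-weighted metric sets.

    Returns a dict with ``matrix`` (raw counts), ``matrix_normalized``
    (row-normalized), ``per_class`` MetricSets, ``macro`` and ``weighted``
    aggregates, and per-class ``support``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or (
        y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    matrix = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(matrix, (y_true, y_pred), 1)
    row_sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix_norm = np.where(row_sums > 0, matrix / np.maximum(row_sums, 1), 0.0)
    per_class = {c: binary_metrics(_ovr_counts(y_true, y_pred, c)) for c in range(n_classes)}
    support = np.array([(y_true == c).sum() for c in range(n_classes)])
    present = support > 0

    def aggregate(weights, name):
        fields = ("precision", "sensitivity", "accuracy", "specificity", "f1", "dice")
        vals = {
            f: float(
                np.average(
                    [getattr(per_class[c], f) for c in range(n_classes) if present[c]],
                    weights=weights[present] if weights is not None else None,
                )
            )
            for f in fields
        }
        return MetricSet(**vals, aggregation=name)

    macro = aggregate(None, "macro")
    weighted = aggregate(support.astype(float), "weighted")
    return {
        "matrix": matrix,
        "matrix_normalized": matrix_norm,
        "per_class": per_class,
        "macro": macro,
        "weighted": weighted,
        "support": support,
        "accuracy": float((y_true == y_pred).mean()),
    }


def roc_pr_curves(y_true, scores, n_classes: int = N_CLASSES) -> dict:
    """One-vs-rest per-class AUC and AP, plus the micro-averaged AP.

    A class absent from ``y_true`` has undefined curves and is reported as
    ``None``.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != n_classes:
        raise ValueError(f"scores must be (n, {n_classes})")
    auc, ap = {}, {}
    for c in range(n_classes):
        t = (y_true == c).astype(int)
        if t.min() == t.max():
            auc[c] = None
            ap[c] = None
            continue
        auc[c] = float(roc_auc_score(t, scores[:, c]))
        ap[c] = float(average_precision_score(t, scores[:, c]))
    onehot = np.eye(n_classes, dtype=int)[y_true]
    micro_ap = float(average_precision_score(onehot.ravel(), scores.ravel()))
    return {"auc": auc, "ap": ap, "micro_ap": micro_ap}


def bootstrap_ci(
    metric_fn,
    y_true,
    y_pred_or_scores,
    iters: int = 1000,
    level: float = 0.95,
    seed: int = 0,
):
    """Seeded percentile bootstrap -> ``(mean, sd, lo, hi)``."""
    y_true = np.asarray(y_true)
    y2 = np.asarray(y_pred_or_scores)
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least two samples to bootstrap")
    rng = np.random.default_rng(seed)
    stats = np.empty(iters)
    for i in range(iters):
        idx = rng.integers(0, n, size=n)
        stats[i] = metric_fn(y_true[idx], y2[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(stats.mean()), float(stats.std(ddof=1)), float(lo), float(hi)


def paired_t_test(fold_scores_a, fold_scores_b):
    """Paired t statistic and two-sided p across cross-validation folds."""
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("fold score vectors must be equal-length 1-D, n >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def stagewise_sensitivity(y_true, y_pred, scores, n_classes: int = N_CLASSES):
    """Per-grade one-vs-rest sensitivity / precision / AUC table.

    Returns a list of dicts, one per grade; grades absent from the truth are
    flagged ``missing``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    curves = roc_pr_curves(y_true, scores, n_classes)
    rows = []
    for c in range(n_classes):
        if (y_true == c).sum() == 0:
            rows.append({"grade": c, "missing": True})
            continue
        m = binary_metrics(_ovr_counts(y_true, y_pred, c))
        rows.append(
            {
                "grade": c,
                "missing": False,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
                "auc": curves["auc"][c],
            }
        )
    return rows
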