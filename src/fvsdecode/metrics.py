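"""Scoring functions shared by every pipeline stage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    mean_absolute_error,
    mean_squared_error,
    roc_auc_score,
)


class MetricsError(ValueError):
    pass


@dataclass
class RegressionMetrics:
    mse: float
    mae: float
    spearman_rho: float | None
    spearman_p: float | None

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
        }


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray
    labels: list
    per_class_recall: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "labels": [str(c) for c in self.labels],
            "confusion": self.confusion.tolist(),
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
        }


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """MSE, MAE and Spearman rank correlation (average ranks for ties).

    Spearman is undefined for constant inputs and reported as missing
    with a warning in that case.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise MetricsError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise MetricsError("need at least 2 observations")
    mse = float(mean_squared_error(y_true, y_pred))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        rho = p = None
    else:
        res = stats.spearmanr(y_true, y_pred)
        rho, p = float(res.statistic), float(res.pvalue)
    return RegressionMetrics(mse=mse, mae=mae, spearman_rho=rho, spearman_p=p)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts; 0 on empty denominators."""
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision set to 0", stacklevel=3)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive truths: recall set to 0", stacklevel=3)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def classification_metrics(
    y_true, y_pred, y_score=None, positive_label=None
) -> ClassificationMetrics:
    """Accuracy, precision/recall/F1, AUC and the confusion matrix.

    Binary problems treat the lexicographically larger label as positive
    unless ``positive_label`` overrides it. Multiclass problems report
    macro-averaged precision/recall/F1 and macro one-vs-rest AUC.
    ``y_score`` columns must align with the sorted class labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricsError("y_true and y_pred must have equal length")
    labels = sorted(np.unique(y_true).tolist())
    extra = set(np.unique(y_pred).tolist()) - set(labels)
    if extra:
        raise MetricsError(f"predicted label(s) {sorted(extra)} absent from y_true")
    confusion = _sk_confusion(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(confusion) / confusion.sum())

    per_class_recall = {}
    for i, lab in enumerate(labels):
        row = confusion[i].sum()
        per_class_recall[lab] = float(confusion[i, i] / row) if row else 0.0

    if len(labels) == 2:
        pos = positive_label if positive_label is not None else labels[-1]
        if pos not in labels:
            raise MetricsError(f"positive_label {pos!r} not among labels {labels}")
        i = labels.index(pos)
        tp = float(confusion[i, i])
        fp = float(confusion[:, i].sum() - tp)
        fn = float(confusion[i].sum() - tp)
        precision, recall, f1 = _prf(tp, fp, fn)
    else:
        ps, rs, fs = [], [], []
        for i in range(len(labels)):
            tp = float(confusion[i, i])
            fp = float(confusion[:, i].sum() - tp)
            fn = float(confusion[i].sum() - tp)
            p_i, r_i, f_i = _prf(tp, fp, fn)
            ps.append(p_i)
            rs.append(r_i)
            fs.append(f_i)
        precision, recall, f1 = map(lambda v: float(np.mean(v)), (ps, rs, fs))

    auc = None
    if y_score is not None:
        score = np.asarray(y_score, dtype=float)
        if len(labels) == 2:
            col = score[:, -1] if score.ndim == 2 else score
            auc = float(roc_auc_score(y_true, col))
        else:
            auc = float(
                roc_auc_score(y_true, score, multi_class="ovr", average="macro")
            )

    return ClassificationMetrics(
        accuracy=accuracy,
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        auc=auc,
        confusion=confusion,
        labels=labels,
        per_class_recall=per_class_recall,
    )
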