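"""Evaluation surface: confusion matrix, scalar metrics, ROC/AUC, shares.

All metrics operate on the four EmA classes I (positive), II (negative),
III (IgA deficient), IV (equivocal), in that fixed order.  Scalar metrics
that reduce the 4-class problem to a binary one (sensitivity, specificity,
precision, F1) are computed one-vs-rest for a designated positive class
(default I) and additionally reported per class plus macro-averaged, so any
aggregation convention can be read off the report.  Ratios with a zero
denominator are reported as ``None`` and flagged, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

CLASSES: tuple[str, ...] = ("I", "II", "III", "IV")


class UndefinedMetricError(ValueError):
    """A ratio whose denominator is zero (e.g. AUC with one-class truth)."""


def confusion(
    true_labels: Sequence[str], pred_labels: Sequence[str]
) -> np.ndarray:
    """4x4 confusion matrix, rows = expert (true) class, columns = predicted."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs {len(pred_labels)}"
        )
    bad = sorted({l for l in (*true_labels, *pred_labels) if l not in CLASSES})
    if bad:
        raise ValueError(f"unknown class labels: {bad}; expected {CLASSES}")
    if not true_labels:
        return np.zeros((4, 4), dtype=np.int64)
    return _sk_confusion(true_labels, pred_labels, labels=list(CLASSES)).astype(
        np.int64
    )


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def _binary_reduction(cm: np.ndarray, k: int) -> dict:
    """One-vs-rest sensitivity/specificity/precision/F1 for class index k."""
    tp = float(cm[k, k])
    fn = float(cm[k, :].sum() - cm[k, k])
    fp = float(cm[:, k].sum() - cm[k, k])
    tn = float(cm.sum() - tp - fn - fp)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    if sens is None or prec is None or (sens + prec) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}


def cohen_kappa(cm: np.ndarray) -> float | None:
    """Chance-corrected agreement from a confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginals.
    Returns ``None`` when p_e = 1 (a single occupied class), where the
    statistic is undefined.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-15:
        return None
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class MetricsReport:
    """Scalar metrics of one confusion matrix (plus optional per-class AUCs).

    ``accuracy + error == 1`` always (same denominator).  ``flags`` lists the
    names of metrics that were undefined for this matrix.
    """

    accuracy: float
    error: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    kappa: float | None
    positive_class: str
    per_class: dict[str, dict]
    macro: dict[str, float | None]
    auc_per_class: dict[str, float | None] = field(default_factory=dict)
    class_shares: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    excluded_equivocal: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error": self.error,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "kappa": self.kappa,
            "positive_class": self.positive_class,
            "per_class": self.per_class,
            "macro": self.macro,
            "auc_per_class": self.auc_per_class,
            "class_shares": self.class_shares,
            "flags": self.flags,
            "excluded_equivocal": self.excluded_equivocal,
        }


def scalar_metrics(
    cm: np.ndarray,
    positive_class: str = "I",
    exclude_equivocal_predictions: bool = False,
) -> MetricsReport:
    """All scalar metrics of a 4x4 (or binary 2x2) confusion matrix.

    ``exclude_equivocal_predictions`` drops samples *predicted* as class IV
    from the accuracy/error denominator (an optional reading of "inconclusive
    results are not counted"); off by default and recorded in the report.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    n = cm.shape[0]
    names = list(CLASSES[:n]) if n <= 4 else [str(i) for i in range(n)]
    if positive_class not in names:
        raise ValueError(f"positive_class {positive_class!r} not in {names}")
    total = float(cm.sum())
    if total <= 0:
        raise ValueError("confusion matrix is empty")

    flags: list[str] = []
    if exclude_equivocal_predictions and "IV" in names:
        iv = names.index("IV")
        denom = total - float(cm[:, iv].sum())
        numer = float(np.trace(cm)) - float(cm[iv, iv])
        accuracy = numer / denom if denom > 0 else None
        if accuracy is None:
            flags.append("accuracy")
            accuracy = float("nan")
    else:
        accuracy = float(np.trace(cm)) / total
    error = 1.0 - accuracy

    per_class = {name: _binary_reduction(cm, i) for i, name in enumerate(names)}
    for name, d in per_class.items():
        for metric, v in d.items():
            if v is None:
                flags.append(f"{name}.{metric}")

    headline = per_class[positive_class]
    kap = cohen_kappa(cm)
    if kap is None:
        flags.append("kappa")

    macro: dict[str, float | None] = {}
    for metric in ("sensitivity", "specificity", "precision", "f1"):
        vals = [d[metric] for d in per_class.values() if d[metric] is not None]
        macro[metric] = float(np.mean(vals)) if vals else None

    return MetricsReport(
        accuracy=accuracy,
        error=error,
        sensitivity=headline["sensitivity"],
        specificity=headline["specificity"],
        precision=headline["precision"],
        f1=headline["f1"],
        kappa=kap,
        positive_class=positive_class,
        per_class=per_class,
        macro=macro,
        flags=flags,
        excluded_equivocal=exclude_equivocal_predictions,
    )


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """One-vs-all AUC by the rank (Mann-Whitney) formulation, ties at 1/2.

    ``truth`` indicates membership of the class whose score is given.
    Raises :class:`UndefinedMetricError` when only one class is present.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.shape != scores.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.all() or (~truth).all():
        raise UndefinedMetricError(
            "AUC undefined: truth contains a single class"
        )
    return float(roc_auc_score(truth, scores))


def roc_points(scores: Sequence[float], truth: Sequence[bool]) -> np.ndarray:
    """Empirical ROC curve as an array of (fpr, tpr, threshold) rows."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or (~truth).all():
        raise UndefinedMetricError("ROC undefined: truth contains a single class")
    fpr, tpr, thr = roc_curve(truth, np.asarray(scores, dtype=np.float64))
    return np.column_stack([fpr, tpr, thr])


def class_shares(class_counts: Sequence[int]) -> list[float]:
    """Percent of the total per class, rounded half-up to two decimals."""
    counts = [int(c) for c in class_counts]
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    return [
        float(
            (Decimal(100 * c) / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for c in counts
    ]
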