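"""Confusion-matrix evaluation suite for the 5-class subtype task.

Per-class one-vs-rest counts (TP, TN, FP, FN) are derived from a C x C
confusion matrix (rows = true class, columns = predicted class) and feed
the standard definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)      [pooled]
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)                        (TPR)
    specificity = TN / (TN + FP)                        (TNR)
    F1          = 2 * precision * recall / (precision + recall)
    balanced accuracy = mean of per-class recalls (binary: (TPR + TNR) / 2)
    Cohen's kappa     = (Po - Pe) / (1 - Pe)

Precision/recall/F1 are support-weighted by default, which makes the
reported accuracy algebraically identical to the weighted recall; balanced
accuracy and AUROC/AUPRC are macro-averaged. AUROC uses trapezoidal
one-vs-rest integration and AUPRC step-wise integration (average
precision), both via scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

#: Report column order used for serialized tables.
REPORT_COLUMNS = [
    "accuracy", "precision", "recall", "f1", "balanced_accuracy",
    "cohens_kappa", "auroc", "auprc",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) int, rows true, cols predicted
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self) -> np.ndarray:
        """Per-class one-vs-rest (TP, FP, FN, TN), shape (C, 4)."""
        cm = self.counts
        tp = np.diag(cm).astype(float)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = cm.sum() - tp - fp - fn
        return np.stack([tp, fp, fn, tn], axis=1)

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    balanced_accuracy: float = float("nan")
    cohens_kappa: float = float("nan")
    auroc: float = float("nan")
    auprc: float = float("nan")
    averaging: str = "weighted"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame([{k: d[k] for k in REPORT_COLUMNS}])


def confusion_matrix(
    y_true, y_pred, classes: tuple[str, ...] | list[str]
) -> ConfusionMatrix:
    """Exact label tally; raises on labels outside ``classes``."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: true={t!r}, pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    bad = den == 0
    if bad.any():
        logger.warning("%s undefined for %d class(es) (zero denominator); set to 0",
                       what, int(bad.sum()))
    np.divide(num, den, out=out, where=~bad)
    return out


def basic_metrics(cm: ConfusionMatrix, averaging: str = "weighted") -> MetricReport:
    """Accuracy, precision, recall, specificity and F1 from a confusion matrix.

    Per-class one-vs-rest values are averaged support-weighted (default) or
    macro. Zero-denominator classes contribute 0 with a logged note.
    """
    if averaging not in ("weighted", "macro"):
        raise ValueError(f"averaging must be 'weighted' or 'macro', got {averaging!r}")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.ovr_counts().T
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")

    support = cm.support().astype(float)
    if averaging == "weighted":
        weights = support / support.sum()
    else:
        weights = np.full(len(support), 1.0 / len(support))
    accuracy = float(np.trace(cm.counts) / cm.total)
    return MetricReport(
        accuracy=accuracy,
        precision=float(precision @ weights),
        recall=float(recall @ weights),
        specificity=float(np.mean(specificity)),  # macro, one-vs-rest
        f1=float(f1 @ weights),
        averaging=averaging,
    )


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls; binary case equals (TPR + TNR)/2."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.ovr_counts().T
    if len(cm.classes) == 2:
        tpr = _safe_div(tp[:1], (tp + fn)[:1], "TPR")[0]
        tnr = _safe_div(tn[:1], (tn + fp)[:1], "TNR")[0]
        return float((tpr + tnr) / 2.0)
    recalls = _safe_div(tp, tp + fn, "balanced-accuracy recall")
    return float(recalls.mean())


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    pe = float((cm.counts.sum(axis=1) / n) @ (cm.counts.sum(axis=0) / n))
    if pe == 1.0:
        logger.warning("degenerate marginals (Pe = 1); kappa set to %s",
                       "1" if po == 1.0 else "0")
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def auroc_auprc(
    y_true, probabilities: np.ndarray, classes: tuple[str, ...] | list[str]
) -> tuple[float, float]:
    """Macro one-vs-rest AUROC and AUPRC from an n x C probability matrix.

    Classes absent from the truth (or without negatives) are skipped with a
    warning; fewer than two distinct truth classes is an error.
    """
    y_true = list(y_true)
    P = np.asarray(probabilities, dtype=np.float64)
    if P.ndim != 2 or P.shape != (len(y_true), len(classes)):
        raise ValueError(f"probability matrix must be {len(y_true)}x{len(classes)}, "
                         f"got {P.shape}")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    present = set(y_true)
    if len(present) < 2:
        raise ValueError("AUROC/AUPRC undefined with fewer than 2 distinct truth classes")
    rocs, prs = [], []
    for i, c in enumerate(classes):
        truth = np.asarray([t == c for t in y_true], dtype=int)
        if truth.sum() == 0 or truth.sum() == len(truth):
            logger.warning("class %r has no positives or no negatives; skipped", c)
            continue
        rocs.append(roc_auc_score(truth, P[:, i]))
        prs.append(average_precision_score(truth, P[:, i]))
    return float(np.mean(rocs)), float(np.mean(prs))


def full_report(
    y_true, y_pred, probabilities: np.ndarray | None,
    classes: tuple[str, ...] | list[str], averaging: str = "weighted",
) -> MetricReport:
    """Complete report from labels and (optionally) predicted probabilities."""
    cm = confusion_matrix(y_true, y_pred, classes)
    report = basic_metrics(cm, averaging)
    report.balanced_accuracy = balanced_accuracy(cm)
    report.cohens_kappa = cohens_kappa(cm)
    if probabilities is not None:
        report.auroc, report.auprc = auroc_auprc(y_true, probabilities, classes)
    return report
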