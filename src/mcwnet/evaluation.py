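"""Confusion matrices, per-class Se/Sp/Pr/F metrics, accuracy, and OVR ROC/AUC.

Conventions: confusion-matrix rows are true classes, columns predictions.
Per-class metrics use the one-vs-rest reduction

    Se = TP/(TP+FN)   Sp = TN/(TN+FP)   Pr = TP/(TP+FP)
    F  = 2*TP/(2*TP+FP+FN)              Acc = trace/total

A zero denominator yields an explicit ``None`` (undefined), never a silent 0.
ROC curves threshold one class's probability against the rest; the AUC is
trapezoidal with tied scores grouped, which equals the Mann-Whitney
pairwise-comparison statistic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRIC_COLUMNS = ["Se", "Sp", "Pr", "F-score", "Acc"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray           # (K, K) ints, rows true, cols predicted
    class_names: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if c.shape != (k, k) or (c < 0).any():
            raise ValueError("counts must be a nonnegative KxK integer matrix")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fn = int(c[class_index].sum() - tp)
        fp = int(c[:, class_index].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, fn, fp, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class ClassMetrics:
    se: float | None
    sp: float | None
    pr: float | None
    f_score: float | None
    auc: float | None = None


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    cm: ConfusionMatrix
    case: str = ""
    ratio: str = ""


def confusion_matrix(true_labels, predicted_labels,
                     class_names: list[str]) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {name: i for i, name in enumerate(class_names)}
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_names))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix,
                           scores: np.ndarray | None = None,
                           true_labels=None) -> MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy.

    When probability ``scores`` and ``true_labels`` are supplied, per-class
    AUC is included as well.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, ClassMetrics] = {}
    for ci, name in enumerate(cm.class_names):
        tp, fn, fp, tn = cm.one_vs_rest(ci)
        auc = None
        if scores is not None and true_labels is not None:
            _, auc = roc_auc_ovr(scores, true_labels, name, cm.class_names)
        per_class[name] = ClassMetrics(
            se=_ratio(tp, tp + fn),
            sp=_ratio(tn, tn + fp),
            pr=_ratio(tp, tp + fp),
            f_score=_ratio(2 * tp, 2 * tp + fp + fn),
            auc=auc,
        )
    accuracy = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(per_class, accuracy, cm)


def roc_auc_ovr(scores: np.ndarray, true_labels, target_class: str,
                class_names: list[str] | None = None
                ) -> tuple[np.ndarray, float | None]:
    """One-vs-rest ROC points and trapezoidal AUC for ``target_class``.

    ``scores`` holds per-sample probability rows; the column used is the
    target class's index in ``class_names`` (inferred from sorted unique
    labels when omitted).  Tied scores are grouped into single threshold
    steps.  Returns (points, auc); both are ``None``-flagged when the class
    has no positives or no negatives.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = list(true_labels)
    if class_names is None:
        class_names = sorted(set(labels))
    col = class_names.index(target_class)
    s = scores[:, col] if scores.ndim == 2 else scores
    if len(s) != len(labels):
        raise ValueError("scores and labels differ in length")
    y = np.array([1 if l == target_class else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        return np.empty((0, 2)), None
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.nonzero(np.diff(s_sorted))[0]          # group tied scores
    keep = np.r_[distinct, len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def report_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Long-form table keyed (case, ratio, class) with Se/Sp/Pr/F/Acc columns."""
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        for name, m in rep.per_class.items():
            rows.append({"case": rep.case, "ratio": rep.ratio, "class": name,
                         "Se": m.se, "Sp": m.sp, "Pr": m.pr,
                         "F-score": m.f_score, "Acc": rep.accuracy})
    return pd.DataFrame(rows, columns=["case", "ratio", "class",
                                       *METRIC_COLUMNS])


def report_tables(reports: list[MetricsReport]) -> tuple[str, str]:
    """(csv_text, human_readable_text) for a collection of reports."""
    frame = report_frame(reports)
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue(), frame.to_string(index=False, float_format="%.4f")
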