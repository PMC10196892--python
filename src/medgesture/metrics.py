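"""Confusion-matrix metric suite: accuracy, precision, recall, F-measure,
specificity, per-activity tables and the binary positive/non-positive
confusion matrix with column-normalised percentages.

Definitions (TP/TN/FP/FN are one-vs-rest counts for the activity of
interest):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    F_beta      = (1 + b^2) * precision * recall / (b^2 * recall + precision)
    specificity = TN / (TN + FP)

A zero denominator yields NaN, rendered as "N/A" in reports — an undefined
ratio is not the same as a score of zero.  Percentage tables round half away
from zero at one decimal, and macro averages are taken over the rounded
one-decimal entries (then rounded again), which is how summary rows in
activity-recognition reports are conventionally assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, UndefinedMetricError
from .sensor_io import CLASS_ORDER


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigurationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_multiclass(true_labels, predicted_labels, class_order=CLASS_ORDER):
    """K x K count matrix; entry (i, j) = true class i predicted as class j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ConfigurationError("true and predicted label lengths differ")
    if not true_labels:
        raise EmptyInputError("no labels to tally")
    index = {lab: i for i, lab in enumerate(class_order)}
    K = len(class_order)
    M = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        M[index[t], index[p]] += 1
    return M


def collapse_binary(matrix, positive_class, class_order=CLASS_ORDER) -> ConfusionCounts:
    """One-vs-rest reduction of a multiclass matrix."""
    if positive_class not in class_order:
        raise ConfigurationError(f"{positive_class!r} not in class_order")
    matrix = np.asarray(matrix)
    k = class_order.index(positive_class)
    tp = int(matrix[k, k])
    fn = int(matrix[k].sum() - tp)
    fp = int(matrix[:, k].sum() - tp)
    tn = int(matrix.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def column_percentages(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(%TP, %FP, %TN, %FN), normalised within predicted-label columns.

    The positive-prediction column holds TP and FP; the negative-prediction
    column holds TN and FN.  Values are rounded to one decimal.
    """
    pos_col = counts.tp + counts.fp
    neg_col = counts.tn + counts.fn
    if pos_col == 0 or neg_col == 0:
        raise UndefinedMetricError("a predicted-label column has zero total")
    return (
        round_half_up(100.0 * counts.tp / pos_col),
        round_half_up(100.0 * counts.fp / pos_col),
        round_half_up(100.0 * counts.tn / neg_col),
        round_half_up(100.0 * counts.fn / neg_col),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def accuracy(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp + counts.tn, counts.total)


def precision(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fp)


def recall(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tn, counts.tn + counts.fp)


def f_measure(precision_value: float, recall_value: float, beta: float = 1.0) -> float:
    if beta <= 0:
        raise ConfigurationError("beta must be positive")
    p, r = precision_value, recall_value
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        return float("nan")
    return (1 + beta**2) * r * p / (beta**2 * r + p)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 96.25 -> 96.3, unlike banker's)."""
    if np.isnan(x):
        return x
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class MetricReport:
    """Per-activity one-vs-rest metric percentages plus the macro-average row.

    ``table`` columns: precision, recall, f_measure, specificity, accuracy —
    all percentages rounded to one decimal, NaN where undefined.  The
    ``average`` row is the unweighted mean of the rounded per-activity
    entries, itself rounded to one decimal (undefined entries excluded).
    """

    table: pd.DataFrame
    average: pd.Series
    beta: float = 1.0

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.loc["average"] = self.average
        out.to_csv(path, na_rep="N/A")


def metric_table(matrix, class_order=CLASS_ORDER, beta: float = 1.0) -> MetricReport:
    """Per-activity metric suite from a multiclass confusion matrix."""
    rows = {}
    for activity in class_order:
        c = collapse_binary(matrix, activity, class_order)
        p, r = precision(c), recall(c)
        rows[activity] = {
            "precision": p,
            "recall": r,
            "f_measure": f_measure(p, r, beta),
            "specificity": specificity(c),
            "accuracy": accuracy(c),
        }
    table = pd.DataFrame(rows).T * 100.0
    table = table.map(round_half_up)
    average = table.mean(axis=0, skipna=True).map(round_half_up)
    return MetricReport(table=table, average=average, beta=beta)


def macro_average(values) -> float:
    """Unweighted mean of one-decimal percentages, rounded to one decimal."""
    vals = [v for v in values if not np.isnan(v)]
    if not vals:
        return float("nan")
    return round_half_up(float(np.mean(vals)))


def binary_report(matrix, positive_class="medication", class_order=CLASS_ORDER) -> pd.DataFrame:
    """Positive/non-positive confusion table with column percentages,
    mirroring the layout counts (percent-of-predicted-column)."""
    c = collapse_binary(matrix, positive_class, class_order)
    ptp, pfp, ptn, pfn = column_percentages(c)
    return pd.DataFrame(
        {
            f"predicted_{positive_class}": [f"{c.tp} ({ptp})", f"{c.fp} ({pfp})"],
            f"predicted_non_{positive_class}": [f"{c.fn} ({pfn})", f"{c.tn} ({ptn})"],
        },
        index=[f"true_{positive_class}", f"true_non_{positive_class}"],
    )
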