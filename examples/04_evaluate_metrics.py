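"""The metric suite on a reference confusion matrix.

Uses the fixed binary medication-vs-rest counts (TP 7412, FN 708, FP 271,
TN 12224) to show each metric and the column-normalised confusion-table
percentages, then a small multiclass example for the per-activity table.
"""

import numpy as np

from medgesture.metrics import (
    ConfusionCounts,
    accuracy,
    column_percentages,
    f_measure,
    metric_table,
    precision,
    recall,
    specificity,
)

counts = ConfusionCounts(tp=7412, tn=12224, fp=271, fn=708)
p, r = precision(counts), recall(counts)
print(f"accuracy    {100 * accuracy(counts):5.1f} %")
print(f"precision   {100 * p:5.1f} %")
print(f"recall      {100 * r:5.1f} %")
print(f"F-measure   {100 * f_measure(p, r):5.1f} %")
print(f"specificity {100 * specificity(counts):5.1f} %")
ptp, pfp, ptn, pfn = column_percentages(counts)
print(f"column-normalised confusion: TP {ptp}%, FP {pfp}%, TN {ptn}%, FN {pfn}%")

# Per-activity table from a 4x4 multiclass matrix (rows = true activity,
# columns = predicted), one-vs-rest per activity:
matrix = np.array([
    [180, 5, 10, 0],
    [8, 150, 2, 0],
    [12, 3, 140, 0],
    [0, 0, 0, 160],
])
report = metric_table(matrix)
print()
print(report.table.to_string())
print("average:")
print(report.average.to_string())
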