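"""Evaluate a scored, labeled interaction set: optimal cutoff, metrics, AUC.

Simulates interactions scored by the pipeline and labeled positive (well
supported, scores drawn high) or negative (scores drawn low), then finds
the cutoff maximizing the Matthews correlation coefficient, reports
accuracy/precision/recall at that cutoff, and the ROC area.  The cutoff is
the score above which one would call an interaction confident; an MCC near
1 means the score separates the classes cleanly.
"""

import random

from miscore import LabeledScore, auc, bin_scores, optimal_cutoff_by_mcc, roc_points

rng = random.Random(1)
labeled = [
    LabeledScore(min(1.0, max(0.0, rng.gauss(0.65, 0.15))), True) for _ in range(120)
] + [
    LabeledScore(min(1.0, max(0.0, rng.gauss(0.35, 0.15))), False) for _ in range(80)
]

cutoff, result = optimal_cutoff_by_mcc(labeled)
points = roc_points(labeled)
print(f"optimal cutoff : {cutoff:.3f}")
print(f"accuracy       : {result.accuracy:.3f}")
print(f"precision      : {result.precision:.3f}")
print(f"recall         : {result.recall:.3f}")
print(f"MCC            : {result.mcc:.3f}")
print(f"ROC AUC        : {auc(points):.3f}")

hist = bin_scores([item.score for item in labeled])
for label, count in zip(hist.bin_labels(), hist.counts):
    print(f"{label}\t{'#' * (count // 2)}{count}")
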