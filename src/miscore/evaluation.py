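"""Binary-classifier evaluation and score-distribution binning.

Given interactions scored in [0, 1] and labeled positive (believed real)
or negative (believed non-interacting), these helpers compute confusion
counts at a cutoff, accuracy/precision/recall and the Matthews correlation
coefficient (MCC), the MCC-optimal cutoff, ROC points with trapezoid AUC,
and decile histograms of score distributions.

Conventions: a score equal to the cutoff predicts positive; an MCC whose
denominator contains a zero factor is reported as 0; an undefined precision
(no predicted positives) is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class LabeledScore:
    score: float
    label: bool  # True = positive

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score}")


@dataclass(frozen=True)
class MetricsResult:
    accuracy: float
    precision: float
    recall: float
    mcc: float
    cutoff: float
    precision_undefined: bool = False


def confusion(labeled: Sequence[LabeledScore], cutoff: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with score >= cutoff predicting positive."""
    if not labeled:
        raise ValueError("empty labeled set")
    tp = fp = tn = fn = 0
    for item in labeled:
        predicted = item.score >= cutoff
        if predicted and item.label:
            tp += 1
        elif predicted and not item.label:
            fp += 1
        elif not predicted and not item.label:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int, cutoff: float = float("nan")) -> MetricsResult:
    """Accuracy, precision, recall and MCC from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative confusion count")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = (tp + tn) / total
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsResult(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        mcc=mcc,
        cutoff=cutoff,
        precision_undefined=precision_undefined,
    )


def _candidate_cutoffs(labeled: Sequence[LabeledScore]) -> list[float]:
    scores = sorted({item.score for item in labeled})
    candidates = {0.0, 1.0}
    candidates.update((a + b) / 2 for a, b in zip(scores, scores[1:]))
    return sorted(candidates)


def optimal_cutoff_by_mcc(labeled: Sequence[LabeledScore]) -> tuple[float, MetricsResult]:
    """Cutoff maximizing MCC over data-driven candidates.

    Candidates are the midpoints of adjacent distinct scores plus {0, 1},
    which covers every achievable confusion table exactly.  Ties resolve to
    the smallest cutoff.
    """
    _require_both_classes(labeled)
    best: tuple[float, MetricsResult] | None = None
    for cutoff in _candidate_cutoffs(labeled):
        result = metrics(*confusion(labeled, cutoff), cutoff=cutoff)
        if best is None or result.mcc > best[1].mcc:
            best = (cutoff, result)
    assert best is not None
    return best


def roc_points(labeled: Sequence[LabeledScore]) -> list[tuple[float, float]]:
    """ROC staircase from (0,0) to (1,1), cutoffs descending through the scores."""
    _require_both_classes(labeled)
    n_pos = sum(1 for item in labeled if item.label)
    n_neg = len(labeled) - n_pos
    points = [(0.0, 0.0)]
    tp = fp = 0
    # sweep scores descending; tied scores move together (one step per value)
    by_score: dict[float, tuple[int, int]] = {}
    for item in labeled:
        pos, neg = by_score.get(item.score, (0, 0))
        by_score[item.score] = (pos + item.label, neg + (not item.label))
    for score in sorted(by_score, reverse=True):
        pos, neg = by_score[score]
        tp += pos
        fp += neg
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoid area under an ROC staircase."""
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def _require_both_classes(labeled: Sequence[LabeledScore]) -> None:
    if not labeled:
        raise ValueError("empty labeled set")
    labels = {item.label for item in labeled}
    if labels != {True, False}:
        raise ValueError("both positive and negative examples are required")


@dataclass(frozen=True)
class ScoreHistogram:
    """Counts over the ten left-open bins (0,0.1], ..., (0.9,1].

    Exact zeros do not fit any left-open bin and land in ``underflow``.
    """

    counts: tuple[int, ...]
    underflow: int

    @property
    def total(self) -> int:
        return self.underflow + sum(self.counts)

    @staticmethod
    def bin_labels() -> list[str]:
        return [f">{i / 10:.1f}-{(i + 1) / 10:.1f}" for i in range(10)]


def bin_scores(scores: Iterable[float]) -> ScoreHistogram:
    """Histogram of scores over (0,0.1], (0.1,0.2], ..., (0.9,1]."""
    counts = [0] * 10
    underflow = 0
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score outside [0,1]: {s}")
        if s == 0.0:
            underflow += 1
            continue
        idx = min(9, math.ceil(s * 10 - 1e-12) - 1)
        counts[idx] += 1
    return ScoreHistogram(counts=tuple(counts), underflow=underflow)
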