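"""Confusion-matrix bookkeeping and the ACC / TPR / FPR metrics.

    ACC = (TP + TN) / (TP + TN + FP + FN)
    TPR = TP / (TP + FN)          (sensitivity)
    FPR = FP / (TN + FP)          (1 - specificity)

A metric whose denominator is zero is *undefined* and raises
:class:`UndefinedMetricError` — it is never silently reported as 0 or 1,
because either default corrupts comparisons between runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "UndefinedMetricError",
    "confusion",
    "metrics",
    "evaluate_reports",
]


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


class Metrics(NamedTuple):
    acc: float
    tpr: float
    fpr: float


def _as_binary(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} values must be binary (0/1)")
    return arr.astype(bool)


def confusion(predicted: Iterable[int], actual: Iterable[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from aligned binary prediction and truth vectors."""
    pred = _as_binary(list(predicted), "predicted")
    act = _as_binary(list(actual), "actual")
    if pred.size != act.size:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {act.size} truths")
    return ConfusionCounts(
        tp=int(np.sum(pred & act)),
        fp=int(np.sum(pred & ~act)),
        tn=int(np.sum(~pred & ~act)),
        fn=int(np.sum(~pred & act)),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, true-positive rate, false-positive rate."""
    if counts.total == 0:
        raise UndefinedMetricError("ACC undefined: no observations")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("TPR undefined: no positive ground truth")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("FPR undefined: no negative ground truth")
    return Metrics(
        acc=(counts.tp + counts.tn) / counts.total,
        tpr=counts.tp / (counts.tp + counts.fn),
        fpr=counts.fp / (counts.tn + counts.fp),
    )


def evaluate_reports(
    reports, truth: Mapping[str, Iterable[str]]
) -> tuple[ConfusionCounts, Metrics]:
    """Score identification reports against known per-query component sets.

    Every (query, library flavor) cell contributes one binary decision:
    predicted positive iff the flavor is a candidate, actually positive iff
    the flavor is in the query's truth set.  Returns the pooled confusion
    counts and the metrics over all cells.
    """
    pred = []
    act = []
    for report in reports:
        if report.query_name not in truth:
            raise KeyError(f"no ground truth for query {report.query_name!r}")
        true_set = set(truth[report.query_name])
        for entry in report.entries:
            pred.append(int(entry.candidate))
            act.append(int(entry.name in true_set))
    counts = confusion(pred, act)
    return counts, metrics(counts)
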