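"""Sequence-level confusion-matrix evaluation of detector output.

A sequence counts as detected-positive iff at least one confirmed fall
event occurs in it (falls are the positive class).  Metrics are the
usual accuracy / sensitivity / specificity / precision, reported as
percentages rounded to two decimals; a metric with an empty denominator
is reported as unavailable (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .detector import DetectionEvent, EventKind

__all__ = ["ConfusionCounts", "MetricsReport", "score_sequences", "metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def _has_confirmed(events: Iterable[DetectionEvent | dict]) -> bool:
    for e in events:
        kind = e.kind.value if isinstance(e, DetectionEvent) else e.get("kind")
        if kind == EventKind.CONFIRMED_FALL.value:
            return True
    return False


def score_sequences(
    events_by_sequence: Mapping[str, Iterable],
    labels_by_sequence: Mapping[str, bool],
) -> ConfusionCounts:
    """Partition sequences into tp/fn/tn/fp.

    ``labels_by_sequence`` maps sequence id -> True for fall sequences.
    Every sequence with events must have a label.
    """
    missing = set(events_by_sequence) - set(labels_by_sequence)
    if missing:
        raise ValueError(f"sequences without ground-truth labels: {sorted(missing)}")
    tp = fn = tn = fp = 0
    for seq_id, is_fall in labels_by_sequence.items():
        detected = _has_confirmed(events_by_sequence.get(seq_id, ()))
        if is_fall:
            tp += detected
            fn += not detected
        else:
            fp += detected
            tn += not detected
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return round(100.0 * num / den, 2)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity and precision in percent
    (2-decimal rounding), with undefined ratios reported as None."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_pct(counts.tp + counts.tn, counts.total),
        sensitivity=_pct(counts.tp, counts.tp + counts.fn),
        specificity=_pct(counts.tn, counts.tn + counts.fp),
        precision=_pct(counts.tp, counts.tp + counts.fp),
    )
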