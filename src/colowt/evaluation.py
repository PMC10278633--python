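"""Frame-level classification metrics and procedure-level time errors.

Sensitivity (true positive rate) and specificity (true negative rate) are
the per-frame metrics:

    TPR = TP / (TP + FN)        TNR = TN / (TN + FP)

Classification metrics are computed on frames at/after the ground-truth
cecum frame, because the pipeline never classifies insertion frames.

The procedure-level time error is normalised by each procedure's true
withdrawal length: a prediction off by 30 s on a 10-minute withdrawal is a
smaller mistake than on a 3-minute one, so errors are reported in seconds
per minute of true withdrawal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    MODEL_POSITIVE_LABELS,
    PhaseLabel,
    PredictionStream,
    ProcedureTimeline,
    positive_mask,
)

__all__ = [
    "ConfusionCounts",
    "UndefinedRateError",
    "sensitivity",
    "specificity",
    "confusion_from_timeline",
    "fn_breakdown",
    "TimeErrorSummary",
    "per_minute_error",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate whose denominator is zero (no positives / no negatives)."""


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_arrays(cls, pred, truth) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if pred.shape != truth.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int(np.count_nonzero(pred & truth)),
            fp=int(np.count_nonzero(pred & ~truth)),
            tn=int(np.count_nonzero(~pred & ~truth)),
            fn=int(np.count_nonzero(~pred & truth)),
        )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); raises :class:`UndefinedRateError` with no positives."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("sensitivity undefined: no positive frames")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); raises :class:`UndefinedRateError` with no negatives."""
    if c.tn + c.fp == 0:
        raise UndefinedRateError("specificity undefined: no negative frames")
    return c.tn / (c.tn + c.fp)


def confusion_from_timeline(
    pred: PredictionStream,
    t: ProcedureTimeline,
    model: str,
    start: Optional[int] = None,
) -> ConfusionCounts:
    """Confusion counts of ``pred`` against ground truth for ``model``.

    ``start`` defaults to the ground-truth cecum frame (0 if the timeline
    has none); earlier frames are not evaluated.
    """
    if len(pred) != t.ntotal:
        raise ValueError(
            f"prediction covers {len(pred)} frames, timeline has {t.ntotal}"
        )
    if start is None:
        start = t.first_cecum_frame() or 0
    truth = positive_mask(t, model)
    return ConfusionCounts.from_arrays(pred.preds[start:], truth[start:])


def fn_breakdown(
    pred: PredictionStream,
    t: ProcedureTimeline,
    model: str,
    start: Optional[int] = None,
) -> dict[PhaseLabel, int]:
    """False negatives attributed to each ground-truth subclass.

    A missed frame counts once for every subclass label of the model's
    group it carries, so the counts can sum to more than the number of FN
    frames when labels overlap.
    """
    if model not in MODEL_POSITIVE_LABELS:
        raise ValueError(f"unknown model {model!r}")
    if len(pred) != t.ntotal:
        raise ValueError("prediction/timeline length mismatch")
    if start is None:
        start = t.first_cecum_frame() or 0
    subclasses = MODEL_POSITIVE_LABELS[model]
    counts: dict[PhaseLabel, int] = {lab: 0 for lab in sorted(subclasses)}
    for ann in t.annotations[start:]:
        if pred.preds[ann.frame_index]:
            continue
        for lab in ann.labels & subclasses:
            counts[lab] += 1
    return counts


@dataclass
class TimeErrorSummary:
    """Per-procedure withdrawal-time errors, normalised per minute.

    ``mean_error_s_per_min`` averages each procedure's
    ``|pred - gt| / (gt / 60)``; ``pooled_error_s_per_min`` divides the
    summed absolute error by the summed ground-truth minutes instead.
    """

    per_procedure: list[dict] = field(default_factory=list)
    mean_error_s_per_min: float = float("nan")
    pooled_error_s_per_min: float = float("nan")
    mean_gt_s: float = float("nan")
    excluded: list[int] = field(default_factory=list)  # indices with gt == 0


def per_minute_error(pairs: Sequence[tuple[float, float]]) -> TimeErrorSummary:
    """Summarise (predicted s, ground-truth s) pairs as seconds-per-minute."""
    rows: list[dict] = []
    excluded: list[int] = []
    for i, (pred_s, gt_s) in enumerate(pairs):
        if gt_s == 0:
            excluded.append(i)
            continue
        if gt_s < 0 or pred_s < 0:
            raise ValueError("times must be non-negative")
        abs_err = abs(pred_s - gt_s)
        rows.append(
            {
                "pred_s": float(pred_s),
                "gt_s": float(gt_s),
                "abs_error_s": abs_err,
                "error_s_per_min": abs_err / (gt_s / 60.0),
            }
        )
    if not rows:
        return TimeErrorSummary(per_procedure=rows, excluded=excluded)
    total_err = sum(r["abs_error_s"] for r in rows)
    total_gt = sum(r["gt_s"] for r in rows)
    return TimeErrorSummary(
        per_procedure=rows,
        mean_error_s_per_min=float(np.mean([r["error_s_per_min"] for r in rows])),
        pooled_error_s_per_min=total_err / (total_gt / 60.0),
        mean_gt_s=total_gt / len(rows),
        excluded=excluded,
    )
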