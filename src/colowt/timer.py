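"""Withdrawal-time computation and the six-minute audit.

The withdrawal time is the time spent actively inspecting the colon after
the cecum is reached, excluding cleaning and therapeutic work:

    t_final = (n_total - n_insertion - n_excluded) / f

where ``n_insertion`` counts the frames strictly before the first cecum
landmark (AO or ICV) frame and ``n_excluded`` counts the frames at or after
it that the OR-merged classifier marks as cleaning/therapeutic/forcep.
Excluding the *union* rather than the per-class sums means a frame that is
simultaneously cleaning and therapeutic is only discarded once; the
per-class counts are still reported for bookkeeping.

Guidelines recommend a minimal withdrawal time of six minutes, so the audit
checks, per procedure, whether prediction and ground truth agree on the
>= 360 s criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import PredictionStream, ProcedureTimeline, positive_mask

__all__ = [
    "WithdrawalEstimate",
    "estimate_withdrawal",
    "ground_truth_withdrawal",
    "six_minute_audit",
    "SixMinuteAudit",
    "format_mmss",
]

SIX_MINUTES_S = 360.0


@dataclass
class WithdrawalEstimate:
    """All quantities entering the withdrawal-time formula for one procedure.

    ``t_final_s`` is ``None`` when the cecum was never detected — without a
    trigger there is no withdrawal phase to time.  ``n_withdrawal`` is the
    retained (exploration) frame count, so that
    ``n_withdrawal + n_insertion + n_excluded_merged == ntotal`` holds in
    exact integer arithmetic.
    """

    ntotal: int
    f: float
    cecum_frame: Optional[int]
    n_insertion: int
    n_excluded_merged: int
    n_cleaning: int
    n_therapeutic: int
    n_forcep: int
    n_withdrawal: int
    t_final_s: Optional[float]

    @property
    def valid(self) -> bool:
        return self.cecum_frame is not None

    @property
    def t_final_mmss(self) -> Optional[str]:
        return None if self.t_final_s is None else format_mmss(self.t_final_s)


def format_mmss(seconds: float) -> str:
    total = int(round(seconds))
    return f"{total // 60}:{total % 60:02d}"


def _count_after(stream: Optional[PredictionStream], start: int) -> int:
    if stream is None:
        return 0
    return int(np.count_nonzero(stream.preds[start:]))


def estimate_withdrawal(
    ntotal: int,
    cecum_frame: Optional[int],
    merged: PredictionStream,
    f: float,
    cleaning: Optional[PredictionStream] = None,
    therapeutic: Optional[PredictionStream] = None,
    forcep: Optional[PredictionStream] = None,
) -> WithdrawalEstimate:
    """Compute the final withdrawal time from the trigger and merged stream.

    Frames strictly before ``cecum_frame`` are insertion; the trigger frame
    itself is the first withdrawal frame.  Positives of the merged stream at
    or after the trigger are excluded.  Per-model streams, when given, only
    feed the per-class bookkeeping counts.
    """
    if f <= 0:
        raise ValueError(f"frame rate must be positive, got {f}")
    if len(merged) != ntotal:
        raise ValueError(
            f"merged stream covers {len(merged)} frames, expected {ntotal}"
        )
    if cecum_frame is not None and not (0 <= cecum_frame < ntotal):
        raise ValueError(
            f"cecum frame {cecum_frame} outside procedure of {ntotal} frames"
        )
    if cecum_frame is None:
        return WithdrawalEstimate(
            ntotal=ntotal,
            f=f,
            cecum_frame=None,
            n_insertion=0,
            n_excluded_merged=0,
            n_cleaning=0,
            n_therapeutic=0,
            n_forcep=0,
            n_withdrawal=0,
            t_final_s=None,
        )
    n_insertion = cecum_frame
    n_excluded = _count_after(merged, cecum_frame)
    n_withdrawal = ntotal - n_insertion - n_excluded
    return WithdrawalEstimate(
        ntotal=ntotal,
        f=f,
        cecum_frame=cecum_frame,
        n_insertion=n_insertion,
        n_excluded_merged=n_excluded,
        n_cleaning=_count_after(cleaning, cecum_frame),
        n_therapeutic=_count_after(therapeutic, cecum_frame),
        n_forcep=_count_after(forcep, cecum_frame),
        n_withdrawal=n_withdrawal,
        t_final_s=n_withdrawal / f,
    )


def ground_truth_withdrawal(t: ProcedureTimeline) -> WithdrawalEstimate:
    """Withdrawal time from the annotations themselves.

    Uses the first annotated AO/ICV frame as the trigger and the union of
    ground-truth cleaning and therapeutic labels as the excluded set.  This
    is the reference value the classifier pipeline is evaluated against.
    """
    cleaning = PredictionStream("cleaning", positive_mask(t, "cleaning"))
    therapeutic = PredictionStream("therapeutic", positive_mask(t, "therapeutic"))
    forcep = PredictionStream("forcep", positive_mask(t, "forcep"))
    merged = PredictionStream("merged", cleaning.preds | therapeutic.preds)
    return estimate_withdrawal(
        ntotal=t.ntotal,
        cecum_frame=t.first_cecum_frame(),
        merged=merged,
        f=t.f,
        cleaning=cleaning,
        therapeutic=therapeutic,
        forcep=forcep,
    )


@dataclass
class SixMinuteAudit:
    """Per-procedure agreement on the six-minute minimum-withdrawal rule."""

    per_procedure: list[tuple[float, float, bool]]  # (pred_s, gt_s, agree)
    n_correct: int
    n_total: int

    @property
    def agreement(self) -> float:
        return self.n_correct / self.n_total if self.n_total else float("nan")


def six_minute_audit(
    estimates: Sequence[tuple[float, float]], threshold_s: float = SIX_MINUTES_S
) -> SixMinuteAudit:
    """Compare predicted and true times against the >= 6 min criterion."""
    rows = []
    for pred_s, gt_s in estimates:
        if pred_s < 0 or gt_s < 0:
            raise ValueError("withdrawal times must be non-negative")
        rows.append((pred_s, gt_s, (pred_s >= threshold_s) == (gt_s >= threshold_s)))
    return SixMinuteAudit(
        per_procedure=rows,
        n_correct=sum(agree for *_, agree in rows),
        n_total=len(rows),
    )
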