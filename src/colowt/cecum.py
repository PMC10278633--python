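"""Cecum landmark detection post-processing and evaluation.

The segmentation model emits a three-channel probability map per frame
(appendiceal orifice, ileocecal valve, background).  Post-processing
assigns each pixel to its argmax channel, extracts 4-connected components
per landmark class, drops speckle below a minimum area fraction, and
returns tight bounding boxes with the mean in-component class probability
as confidence.

Detection of either landmark in a frame triggers the start of withdrawal:
once the cecum is seen, the detection task finishes and phase
classification begins.

Evaluation is frame-level (sensitivity/specificity per class and for
"both"), procedure-level (was the structure ever found), and temporal —
the time to detection

    t_detection = t_model - t_groundtruth

counts the frames between a landmark's first appearance and its first
accepted detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .core import BoundingBox, FrameAnnotation, PhaseLabel, ProcedureTimeline
from .evaluation import ConfusionCounts, UndefinedRateError, sensitivity, specificity

__all__ = [
    "ScoredBox",
    "DetectionFrame",
    "DetectionOutcome",
    "iou",
    "mask_to_boxes",
    "match_boxes",
    "detect_cecum",
    "detection_metrics",
    "DetectionReport",
]

_CHANNEL_LABEL = {0: PhaseLabel.AO, 1: PhaseLabel.ICV}
_BG_CHANNEL = 2


@dataclass(frozen=True)
class ScoredBox:
    """A predicted landmark box with its confidence."""

    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class DetectionFrame:
    """All landmark detections for one frame."""

    frame_index: int
    boxes: list[ScoredBox] = field(default_factory=list)

    def labels(self) -> set[PhaseLabel]:
        return {sb.box.label for sb in self.boxes}


@dataclass
class DetectionOutcome:
    """Per-procedure detection timing for one landmark class."""

    first_gt_frame: Optional[int] = None
    first_detected_frame: Optional[int] = None

    @property
    def t_detection(self) -> Optional[int]:
        if self.first_gt_frame is None or self.first_detected_frame is None:
            return None
        return self.first_detected_frame - self.first_gt_frame


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; symmetric, in [0, 1]."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def mask_to_boxes(
    prob_map: np.ndarray,
    frame_index: int = 0,
    min_area_fraction: float = 0.001,
) -> DetectionFrame:
    """Turn a (H, W, 3) probability map into landmark detection boxes.

    Pixels are assigned to their argmax channel; per landmark class, every
    4-connected component with area >= ``min_area_fraction`` of the frame
    is returned as a tight box whose confidence is the mean class
    probability inside the component.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 3 or prob_map.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) probability map, got shape {prob_map.shape}"
        )
    h, w, _ = prob_map.shape
    min_area = min_area_fraction * h * w
    assigned = np.argmax(prob_map, axis=2)
    boxes: list[ScoredBox] = []
    for channel, lab in _CHANNEL_LABEL.items():
        components = cc_label(assigned == channel, connectivity=1)
        for region in regionprops(components):
            if region.area < min_area:
                continue
            y0, x0, y1, x1 = region.bbox
            mask = components[y0:y1, x0:x1] == region.label
            conf = float(prob_map[y0:y1, x0:x1, channel][mask].mean())
            boxes.append(
                ScoredBox(
                    box=BoundingBox(label=lab, x0=x0, y0=y0, x1=x1, y1=y1),
                    confidence=conf,
                )
            )
    return DetectionFrame(frame_index=frame_index, boxes=boxes)


def match_boxes(
    pred: DetectionFrame, gt: FrameAnnotation, iou_min: float = 0.25
) -> dict[PhaseLabel, ConfusionCounts]:
    """Frame-level confusion per landmark class.

    A class scores TP when at least one predicted box overlaps a
    ground-truth box of the class with IoU >= ``iou_min``; FP when
    predictions exist without a match (or without any ground truth); FN
    when ground truth exists without a match — a frame where both sides
    exist but disagree counts one FP *and* one FN; TN otherwise.
    """
    if not 0.0 <= iou_min <= 1.0:
        raise ValueError(f"iou_min must be in [0, 1], got {iou_min}")
    if pred.frame_index != gt.frame_index:
        raise ValueError(
            f"frame mismatch: detections for {pred.frame_index}, "
            f"annotation for {gt.frame_index}"
        )
    out: dict[PhaseLabel, ConfusionCounts] = {}
    for lab in (PhaseLabel.AO, PhaseLabel.ICV):
        pred_boxes = [sb.box for sb in pred.boxes if sb.box.label == lab]
        gt_boxes = [b for b in gt.boxes if b.label == lab]
        matched = any(
            iou(p, g) >= iou_min for p in pred_boxes for g in gt_boxes
        )
        if matched:
            out[lab] = ConfusionCounts(tp=1)
        else:
            out[lab] = ConfusionCounts(
                fp=1 if pred_boxes else 0,
                fn=1 if gt_boxes else 0,
                tn=1 if not pred_boxes and not gt_boxes else 0,
            )
    return out


def detect_cecum(stream: Iterable[DetectionFrame]) -> Optional[int]:
    """First frame index containing any AO or ICV detection, if any.

    This is the withdrawal trigger: the detection task finishes at this
    frame and phase classification takes over.
    """
    for frame in stream:
        if frame.boxes:
            return frame.frame_index
    return None


def _rate_or_none(fn, counts: ConfusionCounts) -> Optional[float]:
    try:
        return fn(counts)
    except UndefinedRateError:
        return None


@dataclass
class DetectionReport:
    """Aggregate detection metrics over a set of procedures."""

    per_frame: dict[str, dict[str, Optional[float]]]
    per_procedure_sensitivity: dict[str, Optional[float]]
    mean_time_to_detection: dict[str, Optional[float]]
    counts: dict[str, ConfusionCounts]

    def to_dict(self) -> dict:
        return {
            "per_frame": self.per_frame,
            "per_procedure_sensitivity": self.per_procedure_sensitivity,
            "mean_time_to_detection": self.mean_time_to_detection,
            "counts": {
                k: {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for k, c in self.counts.items()
            },
        }


def detection_metrics(
    procedures: Sequence[tuple[Sequence[DetectionFrame], ProcedureTimeline]],
    iou_min: float = 0.25,
    exclude_low_quality: bool = True,
) -> DetectionReport:
    """Frame-, procedure- and time-level detection metrics.

    Rows are "AO", "ICV" and "both".  For the combined row a frame is
    ground-truth positive when either landmark is annotated and predicted
    positive when any landmark box is emitted at all — detecting the cecum
    matters more than which structure was recognised.  Low-quality
    landmark frames are skipped by default, mirroring an evaluation
    restricted to high-quality views.
    """
    if not procedures:
        raise ValueError("need at least one procedure to evaluate")
    keys = ["AO", "ICV", "both"]
    totals = {k: ConfusionCounts() for k in keys}
    proc_detected = {k: 0 for k in keys}
    proc_with_gt = {k: 0 for k in keys}
    t_detections = {k: [] for k in keys}

    for detections, timeline in procedures:
        det_by_frame = {d.frame_index: d for d in detections}
        counts = {k: ConfusionCounts() for k in keys}
        first_gt = {k: None for k in keys}
        first_match = {k: None for k in keys}
        for ann in timeline.annotations:
            if exclude_low_quality and ann.quality == "low":
                continue
            det = det_by_frame.get(ann.frame_index, DetectionFrame(ann.frame_index))
            per_class = match_boxes(det, ann, iou_min=iou_min)
            for lab, key in ((PhaseLabel.AO, "AO"), (PhaseLabel.ICV, "ICV")):
                c = per_class[lab]
                counts[key] += c
                if any(b.label == lab for b in ann.boxes) and first_gt[key] is None:
                    first_gt[key] = ann.frame_index
                if (
                    c.tp
                    and first_gt[key] is not None
                    and first_match[key] is None
                ):
                    first_match[key] = ann.frame_index
            gt_pos = bool(ann.boxes)
            pred_pos = bool(det.boxes)
            counts["both"] += ConfusionCounts(
                tp=int(gt_pos and pred_pos),
                fp=int(pred_pos and not gt_pos),
                fn=int(gt_pos and not pred_pos),
                tn=int(not gt_pos and not pred_pos),
            )
            if gt_pos and first_gt["both"] is None:
                first_gt["both"] = ann.frame_index
            if (
                gt_pos
                and pred_pos
                and first_gt["both"] is not None
                and first_match["both"] is None
            ):
                first_match["both"] = ann.frame_index
        for k in keys:
            totals[k] += counts[k]
            if first_gt[k] is not None:
                proc_with_gt[k] += 1
                if first_match[k] is not None:
                    proc_detected[k] += 1
                    t_detections[k].append(first_match[k] - first_gt[k])

    per_frame = {
        k: {
            "sensitivity": _rate_or_none(sensitivity, totals[k]),
            "specificity": _rate_or_none(specificity, totals[k]),
        }
        for k in keys
    }
    per_proc = {
        k: (proc_detected[k] / proc_with_gt[k] if proc_with_gt[k] else None)
        for k in keys
    }
    mean_ttd = {
        k: (float(np.mean(t_detections[k])) if t_detections[k] else None)
        for k in keys
    }
    return DetectionReport(
        per_frame=per_frame,
        per_procedure_sensitivity=per_proc,
        mean_time_to_detection=mean_ttd,
        counts=totals,
    )
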