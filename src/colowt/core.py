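"""Domain types for colonoscopy procedure timelines.

A colonoscopy is annotated frame by frame with phase labels.  Labels belong
to fixed groups: the *cecum* landmarks (appendiceal orifice, ileocecal valve)
that mark the start of withdrawal, the *cleaning* phases (washing, suction),
the *therapeutic* phases (the polyp-removal workflow plus forcep use), and
the *imaging* modes (narrow-band imaging, with or without near focus).
Cleaning and therapeutic frames are excluded from the withdrawal time; the
imaging labels are bookkeeping only and count as ordinary exploration.

Three binary classifiers operate on the withdrawal: ``cleaning``,
``therapeutic`` and ``forcep``.  The forcep label is deliberately positive
for *both* the therapeutic model and the dedicated forcep model — short
biopsy events need a much shorter temporal window than the long therapeutic
blocks, so they get their own classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PhaseGroup",
    "PhaseLabel",
    "LABEL_GROUP",
    "MODEL_NAMES",
    "MODEL_POSITIVE_LABELS",
    "BoundingBox",
    "FrameAnnotation",
    "ProcedureTimeline",
    "ScoreStream",
    "PredictionStream",
    "ground_truth_positive",
    "positive_mask",
    "validate_timeline",
]


class PhaseGroup(str, Enum):
    CECUM = "cecum"
    CLEANING = "cleaning"
    THERAPEUTIC = "therapeutic"
    IMAGING = "imaging"


class PhaseLabel(str, Enum):
    AO = "AO"
    ICV = "ICV"
    WASHING = "washing"
    SUCTION = "suction"
    INJECTION = "injection"
    OPTIMISING_POSITION = "optimising_position"
    POLYPECTOMY = "polypectomy"
    INSPECTING_RESECTION = "inspecting_resection"
    FORCEP = "forcep"
    NBI = "NBI"
    NBI_NF = "NBI_NF"

    @property
    def group(self) -> PhaseGroup:
        return LABEL_GROUP[self]


#: Total, fixed label-to-group mapping.
LABEL_GROUP: dict[PhaseLabel, PhaseGroup] = {
    PhaseLabel.AO: PhaseGroup.CECUM,
    PhaseLabel.ICV: PhaseGroup.CECUM,
    PhaseLabel.WASHING: PhaseGroup.CLEANING,
    PhaseLabel.SUCTION: PhaseGroup.CLEANING,
    PhaseLabel.INJECTION: PhaseGroup.THERAPEUTIC,
    PhaseLabel.OPTIMISING_POSITION: PhaseGroup.THERAPEUTIC,
    PhaseLabel.POLYPECTOMY: PhaseGroup.THERAPEUTIC,
    PhaseLabel.INSPECTING_RESECTION: PhaseGroup.THERAPEUTIC,
    PhaseLabel.FORCEP: PhaseGroup.THERAPEUTIC,
    PhaseLabel.NBI: PhaseGroup.IMAGING,
    PhaseLabel.NBI_NF: PhaseGroup.IMAGING,
}

#: Names of the three binary classifiers.
MODEL_NAMES: tuple[str, ...] = ("cleaning", "therapeutic", "forcep")

#: Ground-truth positive label set for each classifier.  The therapeutic
#: model includes the forcep subclass; the forcep model sees only forcep.
MODEL_POSITIVE_LABELS: dict[str, frozenset[PhaseLabel]] = {
    "cleaning": frozenset({PhaseLabel.WASHING, PhaseLabel.SUCTION}),
    "therapeutic": frozenset(
        {
            PhaseLabel.INJECTION,
            PhaseLabel.OPTIMISING_POSITION,
            PhaseLabel.POLYPECTOMY,
            PhaseLabel.INSPECTING_RESECTION,
            PhaseLabel.FORCEP,
        }
    ),
    "forcep": frozenset({PhaseLabel.FORCEP}),
}

_CECUM_LABELS = frozenset({PhaseLabel.AO, PhaseLabel.ICV})


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based, half-open pixel coordinates.

    ``x`` is the column index, ``y`` the row index; the box covers
    ``[x0, x1) x [y0, y1)``.
    """

    label: PhaseLabel
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.label not in _CECUM_LABELS:
            raise ValueError(f"bounding boxes are AO/ICV only, got {self.label}")

    @property
    def is_degenerate(self) -> bool:
        return not (self.x0 < self.x1 and self.y0 < self.y1)

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class FrameAnnotation:
    """Ground-truth annotation of a single video frame.

    An empty label set means exploration (the negative class for every
    classifier).  A frame may carry several labels at once, e.g. washing
    during a therapeutic block.  ``quality`` is only meaningful on frames
    showing a cecum landmark.
    """

    frame_index: int
    labels: frozenset[PhaseLabel] = frozenset()
    boxes: tuple[BoundingBox, ...] = ()
    quality: Optional[str] = None  # "high" | "low" when AO/ICV present


@dataclass
class ProcedureTimeline:
    """Dense per-frame ground truth for one procedure.

    ``annotations[i].frame_index == i`` for every frame; one procedure per
    patient is assumed, but ``patient_id`` is kept so split checks stay
    explicit.
    """

    procedure_id: str
    patient_id: str
    annotations: list[FrameAnnotation]
    f: float = 30.0  # frames per second
    frame_size: Optional[tuple[int, int]] = None  # (height, width)

    @property
    def ntotal(self) -> int:
        return len(self.annotations)

    def first_cecum_frame(self) -> Optional[int]:
        """Index of the first frame carrying an AO or ICV label, if any."""
        for ann in self.annotations:
            if ann.labels & _CECUM_LABELS:
                return ann.frame_index
        return None


@dataclass
class ScoreStream:
    """Raw per-frame positive-class probabilities from one binary model."""

    model: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one value per frame")
        if self.scores.size and (
            self.scores.min() < 0.0 or self.scores.max() > 1.0
        ):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class PredictionStream:
    """Per-frame binary decisions at some stage of the pipeline."""

    model: str
    preds: np.ndarray

    def __post_init__(self) -> None:
        self.preds = np.asarray(self.preds, dtype=bool)
        if self.preds.ndim != 1:
            raise ValueError("preds must be one value per frame")

    def __len__(self) -> int:
        return int(self.preds.size)


def ground_truth_positive(frame: FrameAnnotation, model: str) -> bool:
    """Whether ``frame`` is a positive example for ``model``.

    Positive means the frame carries any subclass label of the model's
    group; exploration and imaging-only frames are negative for all three
    models.
    """
    if model not in MODEL_POSITIVE_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    return bool(frame.labels & MODEL_POSITIVE_LABELS[model])


def positive_mask(timeline: ProcedureTimeline, model: str) -> np.ndarray:
    """Boolean ground-truth vector over all frames of ``timeline``."""
    if model not in MODEL_POSITIVE_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    wanted = MODEL_POSITIVE_LABELS[model]
    return np.fromiter(
        (bool(ann.labels & wanted) for ann in timeline.annotations),
        dtype=bool,
        count=timeline.ntotal,
    )


def validate_timeline(t: ProcedureTimeline) -> list[str]:
    """Check every timeline invariant; return human-readable violations.

    Violations are returned, not raised, so a whole annotation file can be
    audited in one pass.
    """
    violations: list[str] = []
    if t.f <= 0:
        violations.append(f"frame rate must be positive, got {t.f}")
    for pos, ann in enumerate(t.annotations):
        if ann.frame_index != pos:
            violations.append(
                f"frame {pos}: annotations not dense/ordered "
                f"(found frame_index {ann.frame_index})"
            )
        box_labels = {b.label for b in ann.boxes}
        missing = box_labels - ann.labels
        if missing:
            violations.append(
                f"frame {ann.frame_index}: box label(s) "
                f"{sorted(l.value for l in missing)} not in frame labels"
            )
        for b in ann.boxes:
            if b.is_degenerate:
                violations.append(
                    f"frame {ann.frame_index}: degenerate {b.label.value} box "
                    f"[{b.x0},{b.x1})x[{b.y0},{b.y1})"
                )
                continue
            if t.frame_size is not None:
                h, w = t.frame_size
                if b.x0 < 0 or b.y0 < 0 or b.x1 > w or b.y1 > h:
                    violations.append(
                        f"frame {ann.frame_index}: box "
                        f"[{b.x0},{b.x1})x[{b.y0},{b.y1}) outside {w}x{h} frame"
                    )
        has_cecum = bool(ann.labels & _CECUM_LABELS)
        if ann.quality is not None and not has_cecum:
            violations.append(
                f"frame {ann.frame_index}: quality set on a frame without AO/ICV"
            )
        if ann.quality is not None and ann.quality not in ("high", "low"):
            violations.append(
                f"frame {ann.frame_index}: quality must be 'high' or 'low', "
                f"got {ann.quality!r}"
            )
    return violations
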