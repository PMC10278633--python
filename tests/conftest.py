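import numpy as np
import pytest

from colowt.core import (
    BoundingBox,
    FrameAnnotation,
    PhaseLabel,
    ProcedureTimeline,
)
from colowt.synthetic import DurationSpec, NoiseSpec, SimulationConfig


def make_timeline(spans, f=30.0, frame_size=(64, 64), boxes_at=None):
    """Hand-rolled timeline from (n_frames, labels) spans.

    ``boxes_at`` maps frame index -> list of BoundingBox; cecum labels are
    added automatically for boxed frames.
    """
    boxes_at = boxes_at or {}
    annotations = []
    i = 0
    for n, labels in spans:
        for _ in range(n):
            boxes = tuple(boxes_at.get(i, ()))
            labs = frozenset(labels) | {b.label for b in boxes}
            annotations.append(
                FrameAnnotation(
                    frame_index=i,
                    labels=labs,
                    boxes=boxes,
                    quality="high" if boxes else None,
                )
            )
            i += 1
    return ProcedureTimeline(
        procedure_id="proc-test",
        patient_id="patient-test",
        annotations=annotations,
        f=f,
        frame_size=frame_size,
    )


@pytest.fixture
def fast_config():
    """Short simulated procedure (~1 min) for quick structural tests."""
    return SimulationConfig(
        seed=42,
        insertion=DurationSpec(10.0, 3.0),
        exploration=DurationSpec(30.0, 8.0),
        cleaning_rate_per_min=3.0,
        cleaning_duration=DurationSpec(2.0, 1.0),
        therapeutic_subphases={
            PhaseLabel.INJECTION: DurationSpec(2.0, 1.0),
            PhaseLabel.OPTIMISING_POSITION: DurationSpec(4.0, 2.0),
            PhaseLabel.POLYPECTOMY: DurationSpec(6.0, 3.0),
            PhaseLabel.INSPECTING_RESECTION: DurationSpec(4.0, 2.0),
        },
        forcep_duration=DurationSpec(2.0, 1.0),
        cecum_visible_span_s=1.0,
        frame_size=(64, 64),
    )


@pytest.fixture
def noiseless_config(fast_config):
    return SimulationConfig(
        **{
            **fast_config.__dict__,
            "noise": {
                m: NoiseSpec(1.0, 1.0, 0.0)
                for m in ("cleaning", "therapeutic", "forcep")
            },
        }
    )


def ao_box(x0=5, y0=5, x1=20, y1=25):
    return BoundingBox(PhaseLabel.AO, x0, y0, x1, y1)


def icv_box(x0=40, y0=10, x1=60, y1=30):
    return BoundingBox(PhaseLabel.ICV, x0, y0, x1, y1)
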