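"""Synthetic colonoscopy procedures with noisy classifier emissions.

Real full-procedure videos are private clinical data, so every downstream
stage is exercised on simulated procedures instead.  A simulated timeline
has the canonical structure of a screening colonoscopy:

* an insertion prefix with no labels (scope travelling to the cecum);
* a cecum event — AO and/or ICV landmarks visible, with bounding boxes,
  over a short span at the start of withdrawal;
* a withdrawal region consisting of exploration frames interleaved with
  short cleaning bursts (washing/suction, at any time), ordered therapeutic
  blocks (injection -> optimising position -> polypectomy -> inspecting
  resection) and short forcep events (biopsies).

Cleaning bursts may overlay therapeutic frames (dual-labelled frames), so
the double-count hazard of naive per-class subtraction is exercised.  The
ground-truth exploration time is exact by construction: excluded phases are
spliced in as extra frames (or overlaid on other excluded frames), never on
exploration frames.

Classifier emissions are per-frame positive-class probabilities with two
noise mechanisms: independent per-frame misclassification calibrated to
sensitivity/specificity targets at cut-point 0.5, and a two-state Markov
burst process that flips short stretches of frames — the short noisy
prediction runs the temporal majority filter exists to remove.

Default durations emulate the reported per-procedure budget: roughly
7:35 min of true exploration, 2:59 of cleaning and 3:21 of therapeutic
work, at 30 fps.  All durations are log-normal (positive, right-skewed),
truncated at one frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from .core import (
    BoundingBox,
    FrameAnnotation,
    MODEL_NAMES,
    PhaseLabel,
    ProcedureTimeline,
    ScoreStream,
    positive_mask,
)

__all__ = [
    "DurationSpec",
    "NoiseSpec",
    "SimulationConfig",
    "generate_timeline",
    "emit_scores",
    "emit_mask",
    "emit_masks",
]

#: Fixed order of the therapeutic sub-phases within a block.
THERAPEUTIC_ORDER: tuple[PhaseLabel, ...] = (
    PhaseLabel.INJECTION,
    PhaseLabel.OPTIMISING_POSITION,
    PhaseLabel.POLYPECTOMY,
    PhaseLabel.INSPECTING_RESECTION,
)


@dataclass(frozen=True)
class DurationSpec:
    """Log-normal duration in seconds, truncated below at one frame."""

    mean_s: float
    sd_s: float

    def __post_init__(self) -> None:
        if self.mean_s <= 0 or self.sd_s < 0:
            raise ValueError("durations need positive mean and non-negative sd")

    def sample_frames(self, rng: np.random.Generator, f: float) -> int:
        if self.sd_s == 0:
            seconds = self.mean_s
        else:
            cv2 = (self.sd_s / self.mean_s) ** 2
            sigma = math.sqrt(math.log1p(cv2))
            mu = math.log(self.mean_s) - 0.5 * sigma**2
            seconds = float(rng.lognormal(mu, sigma))
        return max(1, int(round(seconds * f)))


@dataclass(frozen=True)
class NoiseSpec:
    """Operating point and burst noise for one simulated classifier.

    ``sensitivity``/``specificity`` are the rates a 0.5 cut-point converges
    to on ground-truth positive/negative frames.  Bursts are a two-state
    Markov process: each frame enters a burst with probability
    ``burst_flip_prob`` and bursts last ``burst_mean_length`` frames on
    average (geometric); inside a burst the emitted score is mirrored to
    the wrong side of 0.5.
    """

    sensitivity: float
    specificity: float
    burst_flip_prob: float = 0.0
    burst_mean_length: float = 3.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "burst_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.burst_mean_length < 1:
            raise ValueError("burst_mean_length must be >= 1 frame")


def _default_noise() -> dict[str, NoiseSpec]:
    # Operating points of the three classifiers before temporal filtering.
    return {
        "cleaning": NoiseSpec(sensitivity=0.8040, specificity=0.8876),
        "therapeutic": NoiseSpec(sensitivity=0.9191, specificity=0.8497),
        "forcep": NoiseSpec(sensitivity=0.8813, specificity=0.9938),
    }


def _default_therapeutic_subphases() -> dict[PhaseLabel, DurationSpec]:
    return {
        PhaseLabel.INJECTION: DurationSpec(20.0, 10.0),
        PhaseLabel.OPTIMISING_POSITION: DurationSpec(40.0, 20.0),
        PhaseLabel.POLYPECTOMY: DurationSpec(60.0, 30.0),
        PhaseLabel.INSPECTING_RESECTION: DurationSpec(40.0, 20.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of the procedure simulator.

    The defaults describe a screening procedure with about 5 minutes of
    insertion, 7:35 of exploration, one to two polyp resections (~3:21 of
    therapeutic work) and ~3 cleaning bursts per minute of withdrawal
    totalling ~2:59.
    """

    seed: int = 0
    f: float = 30.0
    frame_size: tuple[int, int] = (248, 248)  # (height, width)
    insertion: DurationSpec = field(default_factory=lambda: DurationSpec(300.0, 90.0))
    exploration: DurationSpec = field(default_factory=lambda: DurationSpec(455.0, 120.0))
    cleaning_rate_per_min: float = 2.7
    cleaning_duration: DurationSpec = field(
        default_factory=lambda: DurationSpec(6.6, 4.0)
    )
    cleaning_overlap_prob: float = 0.2
    therapeutic_block_mean_count: float = 1.25
    therapeutic_subphases: dict[PhaseLabel, DurationSpec] = field(
        default_factory=_default_therapeutic_subphases
    )
    forcep_event_mean_count: float = 1.0
    forcep_duration: DurationSpec = field(default_factory=lambda: DurationSpec(8.0, 4.0))
    ao_prob: float = 0.9
    icv_prob: float = 0.8
    cecum_visible_span_s: float = 2.0
    noise: dict[str, NoiseSpec] = field(default_factory=_default_noise)

    def __post_init__(self) -> None:
        for name in ("cleaning_overlap_prob", "ao_prob", "icv_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ao_prob == 0.0 and self.icv_prob == 0.0:
            raise ValueError("at least one of ao_prob/icv_prob must be positive")
        if self.f <= 0:
            raise ValueError("frame rate must be positive")
        if self.cleaning_rate_per_min < 0:
            raise ValueError("cleaning rate must be non-negative")
        if self.therapeutic_block_mean_count < 0 or self.forcep_event_mean_count < 0:
            raise ValueError("event counts must be non-negative")
        if self.cecum_visible_span_s <= 0:
            raise ValueError("cecum visible span must be positive")
        unknown = set(self.noise) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"noise specs for unknown models: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _sample_box(
    rng: np.random.Generator, label: PhaseLabel, frame_size: tuple[int, int], half: str
) -> BoundingBox:
    """Random landmark box; AO in the left half, ICV in the right, so the
    two never overlap in a synthetic probability map."""
    h, w = frame_size
    x_lo, x_hi = (0, w // 2) if half == "left" else (w // 2, w)
    bw = int(rng.integers(max(4, (x_hi - x_lo) // 8), max(5, (x_hi - x_lo) // 2)))
    bh = int(rng.integers(max(4, h // 8), max(5, h // 2)))
    x0 = int(rng.integers(x_lo, max(x_lo + 1, x_hi - bw)))
    y0 = int(rng.integers(0, max(1, h - bh)))
    return BoundingBox(label=label, x0=x0, y0=y0, x1=x0 + bw, y1=y0 + bh)


def generate_timeline(cfg: SimulationConfig) -> ProcedureTimeline:
    """Simulate one fully annotated procedure; deterministic given the seed.

    The returned timeline satisfies every timeline invariant and its
    ground-truth withdrawal time equals the sampled exploration duration
    exactly (excluded phases are inserted as extra frames or overlaid on
    already-excluded frames, never on exploration frames).
    """
    rng = np.random.default_rng(cfg.seed)
    f = cfg.f

    n_insertion = cfg.insertion.sample_frames(rng, f)
    n_exploration = cfg.exploration.sample_frames(rng, f)

    # Withdrawal label track, one label-set per frame; starts as exploration.
    withdrawal: list[frozenset[PhaseLabel]] = [frozenset()] * n_exploration

    # Therapeutic blocks: positions drawn in exploration coordinates and
    # spliced from the right so blocks never nest inside each other.
    n_blocks = int(rng.poisson(cfg.therapeutic_block_mean_count))
    block_positions = sorted(
        (int(rng.integers(0, n_exploration + 1)) for _ in range(n_blocks)),
        reverse=True,
    )
    for pos in block_positions:
        block: list[frozenset[PhaseLabel]] = []
        for lab in THERAPEUTIC_ORDER:
            dur = cfg.therapeutic_subphases[lab].sample_frames(rng, f)
            block.extend([frozenset({lab})] * dur)
        withdrawal[pos:pos] = block

    # Forcep events: may land inside a therapeutic block (forcep is itself
    # a therapeutic subclass), so positions are drawn over the whole track.
    n_forcep = int(rng.poisson(cfg.forcep_event_mean_count))
    for _ in range(n_forcep):
        dur = cfg.forcep_duration.sample_frames(rng, f)
        pos = int(rng.integers(0, len(withdrawal) + 1))
        withdrawal[pos:pos] = [frozenset({PhaseLabel.FORCEP})] * dur

    # Cleaning bursts: count follows the rate per withdrawal minute; each
    # burst is either overlaid on therapeutic frames (dual labels) or
    # spliced in as pure cleaning frames.
    therapeutic_set = frozenset(THERAPEUTIC_ORDER) | {PhaseLabel.FORCEP}
    withdrawal_min = len(withdrawal) / f / 60.0
    n_bursts = int(rng.poisson(cfg.cleaning_rate_per_min * withdrawal_min))
    for _ in range(n_bursts):
        dur = cfg.cleaning_duration.sample_frames(rng, f)
        lab = PhaseLabel.WASHING if rng.random() < 0.5 else PhaseLabel.SUCTION
        ther_idx = [
            i for i, labs in enumerate(withdrawal) if labs & therapeutic_set
        ]
        if ther_idx and rng.random() < cfg.cleaning_overlap_prob:
            start = ther_idx[int(rng.integers(0, len(ther_idx)))]
            i = start
            while i < len(withdrawal) and i - start < dur:
                if not withdrawal[i] & therapeutic_set:
                    break  # overlay stays inside the excluded stretch
                withdrawal[i] = withdrawal[i] | {lab}
                i += 1
        else:
            pos = int(rng.integers(0, len(withdrawal) + 1))
            withdrawal[pos:pos] = [frozenset({lab})] * dur

    # Cecum event at the start of withdrawal.
    has_ao = rng.random() < cfg.ao_prob
    has_icv = rng.random() < cfg.icv_prob
    if not (has_ao or has_icv):
        has_ao = True
    span = max(1, int(round(cfg.cecum_visible_span_s * f)))
    span = min(span, len(withdrawal))
    boxes: list[BoundingBox] = []
    if has_ao:
        boxes.append(_sample_box(rng, PhaseLabel.AO, cfg.frame_size, "left"))
    if has_icv:
        boxes.append(_sample_box(rng, PhaseLabel.ICV, cfg.frame_size, "right"))
    cecum_labels = frozenset(b.label for b in boxes)

    annotations: list[FrameAnnotation] = []
    for i in range(n_insertion):
        annotations.append(FrameAnnotation(frame_index=i))
    for j, labs in enumerate(withdrawal):
        idx = n_insertion + j
        if j < span:
            annotations.append(
                FrameAnnotation(
                    frame_index=idx,
                    labels=labs | cecum_labels,
                    boxes=tuple(boxes),
                    quality="high",
                )
            )
        else:
            annotations.append(FrameAnnotation(frame_index=idx, labels=labs))

    return ProcedureTimeline(
        procedure_id=f"sim-{cfg.seed:010d}",
        patient_id=f"patient-{cfg.seed:010d}",
        annotations=annotations,
        f=f,
        frame_size=cfg.frame_size,
    )


_MODEL_STREAM_SALT = {"cleaning": 1, "therapeutic": 2, "forcep": 3}


def emit_scores(
    t: ProcedureTimeline, cfg: SimulationConfig, model: str
) -> ScoreStream:
    """Noisy per-frame positive-class probabilities for one classifier.

    Scores land on the correct side of 0.5 with probability equal to the
    model's sensitivity (on ground-truth positives) or specificity (on
    negatives); the magnitude within each half is Beta-distributed.  A
    seeded Markov burst process then mirrors stretches of frames across
    0.5, producing the short runs of wrong predictions that the temporal
    majority filter is designed to remove.  Deterministic given
    ``(cfg.seed, model)``.
    """
    if model not in _MODEL_STREAM_SALT:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    spec = cfg.noise[model]
    rng = np.random.default_rng([cfg.seed, _MODEL_STREAM_SALT[model]])
    gt = positive_mask(t, model)
    n = gt.size

    correct_prob = np.where(gt, spec.sensitivity, spec.specificity)
    correct = rng.random(n) < correct_prob
    # side == True -> score above 0.5
    side = np.where(correct, gt, ~gt)
    magnitude = rng.beta(2.0, 2.0, size=n) * 0.5  # in (0, 0.5)
    scores = np.where(side, 0.5 + magnitude, 0.5 - magnitude)

    if spec.burst_flip_prob > 0.0:
        enter = rng.random(n) < spec.burst_flip_prob
        leave = rng.random(n) < 1.0 / spec.burst_mean_length
        in_burst = np.zeros(n, dtype=bool)
        state = False
        for i in range(n):
            if state:
                state = not leave[i]
            if not state and enter[i]:
                state = True
            in_burst[i] = state
        scores = np.where(in_burst, 1.0 - scores, scores)

    return ScoreStream(model=model, scores=np.clip(scores, 0.0, 1.0))


def emit_mask(
    ann: FrameAnnotation, frame_size: tuple[int, int]
) -> np.ndarray:
    """Synthetic segmentation probability map for one frame.

    Returns an ``(H, W, 3)`` float array with channels (AO, ICV,
    background) summing to one per pixel.  Each ground-truth box is filled
    with probability 0.9 in its class channel (one connected blob exactly
    covering the box); frames without boxes are pure background.
    """
    h, w = frame_size
    m = np.zeros((h, w, 3), dtype=float)
    m[:, :, 2] = 1.0
    channel = {PhaseLabel.AO: 0, PhaseLabel.ICV: 1}
    for b in ann.boxes:
        c = channel[b.label]
        m[b.y0 : b.y1, b.x0 : b.x1, c] = 0.9
        m[b.y0 : b.y1, b.x0 : b.x1, 2] = 0.1
    return m


def emit_masks(
    t: ProcedureTimeline,
    cfg: SimulationConfig,
    frames: Optional[Iterable[int]] = None,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(frame_index, probability map)`` for the requested frames.

    Defaults to all frames; maps are generated lazily because a full
    procedure holds tens of thousands of frames.
    """
    if frames is None:
        frames = range(t.ntotal)
    for i in frames:
        yield i, emit_mask(t.annotations[i], cfg.frame_size)
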