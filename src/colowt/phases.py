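"""Temporal post-processing of per-frame classifier scores.

Each binary classifier emits one positive-class probability per frame.  The
pipeline turns those into binary decisions in a fixed order:

    binarize -> majority-vote filter -> confidence threshold -> logical OR

The majority vote over a window of ``n`` frames centred on each frame
removes short, isolated misclassifications; the confidence threshold then
demotes surviving positives whose raw network score is low.  Cleaning and
forcep events last seconds, so they use a short window (default 20 frames);
therapeutic blocks last minutes and use a long one (default 200 frames).
Finally the three streams are OR-merged: a frame is discarded from the
withdrawal time if *any* model claims it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MODEL_NAMES, PredictionStream, ScoreStream

__all__ = [
    "FilterConfig",
    "binarize",
    "majority_vote_filter",
    "apply_threshold",
    "merge_or",
    "classify_stream",
]


def _default_windows() -> dict[str, int]:
    return {"cleaning": 20, "therapeutic": 200, "forcep": 20}


def _default_thresholds() -> dict[str, float]:
    return {"cleaning": 0.15, "therapeutic": 0.15, "forcep": 0.15}


@dataclass
class FilterConfig:
    """Per-model temporal-filter parameters.

    Defaults: window 20 and threshold 0.15 for cleaning and forcep, window
    200 and threshold 0.15 for therapeutic; scores are binarized at 0.5
    (the argmax of a two-class softmax).
    """

    windows: dict[str, int] = field(default_factory=_default_windows)
    thresholds: dict[str, float] = field(default_factory=_default_thresholds)
    cut_point: float = 0.5

    def __post_init__(self) -> None:
        for m in MODEL_NAMES:
            if self.windows.get(m, 1) < 1:
                raise ValueError(f"window for {m} must be >= 1")
            th = self.thresholds.get(m, 0.0)
            if not 0.0 <= th <= 1.0:
                raise ValueError(f"threshold for {m} must be in [0, 1]")

    @classmethod
    def identity(cls) -> "FilterConfig":
        """Configuration whose vote filter is the identity (window 1)."""
        return cls(
            windows={m: 1 for m in MODEL_NAMES},
            thresholds={m: 0.0 for m in MODEL_NAMES},
        )


def binarize(s: ScoreStream, cut_point: float = 0.5) -> PredictionStream:
    """Frame positive iff its score strictly exceeds ``cut_point``."""
    return PredictionStream(model=s.model, preds=s.scores > cut_point)


def majority_vote_filter(p: PredictionStream, n: int) -> PredictionStream:
    """Replace each frame by the majority class of its centred window.

    The window for frame ``i`` covers ``[i - ceil((n-1)/2), i + floor((n-1)/2)]``
    (for even ``n`` the extra frame sits on the left), intersected with the
    valid frame range — the window shrinks at the stream boundaries rather
    than being padded.  Exact ties vote negative, which favours specificity.
    ``n = 1`` is the identity.
    """
    if n < 1:
        raise ValueError(f"window size must be >= 1, got {n}")
    x = p.preds
    m = x.size
    if m == 0 or n == 1:
        return PredictionStream(model=p.model, preds=x.copy())
    left = -((1 - n) // 2)  # ceil((n-1)/2)
    right = (n - 1) // 2
    csum = np.concatenate(([0], np.cumsum(x.astype(np.int64))))
    idx = np.arange(m)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, m - 1)
    positives = csum[hi + 1] - csum[lo]
    window = hi - lo + 1
    return PredictionStream(model=p.model, preds=2 * positives > window)


def apply_threshold(
    filtered: PredictionStream, raw: ScoreStream, theta: float
) -> PredictionStream:
    """Demote filtered positives whose raw score falls below ``theta``.

    Thresholding is one-directional: a positive survives iff its raw
    network score is >= ``theta``; negative frames are never promoted.
    ``theta = 0`` is the identity.
    """
    if len(filtered) != len(raw):
        raise ValueError(
            f"stream length mismatch: {len(filtered)} predictions "
            f"vs {len(raw)} scores"
        )
    return PredictionStream(
        model=filtered.model, preds=filtered.preds & (raw.scores >= theta)
    )


def merge_or(*streams: PredictionStream) -> PredictionStream:
    """Combine per-model decisions with a logical OR.

    A frame is excluded from the withdrawal time if any model marks it
    positive, because several phases can happen at the same time.
    """
    if not streams:
        raise ValueError("need at least one stream to merge")
    lengths = {len(s) for s in streams}
    if len(lengths) != 1:
        raise ValueError(f"stream length mismatch: {sorted(lengths)}")
    merged = streams[0].preds.copy()
    for s in streams[1:]:
        merged |= s.preds
    return PredictionStream(model="merged", preds=merged)


def classify_stream(
    s: ScoreStream, n: int, theta: float, cut_point: float = 0.5
) -> PredictionStream:
    """Full per-model chain: binarize, vote-filter, then threshold."""
    return apply_threshold(majority_vote_filter(binarize(s, cut_point), n), s, theta)
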