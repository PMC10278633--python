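"""Cluster-stratified dataset splitting and class-balanced subsampling.

Procedures differ wildly in composition (some are all exploration, some
mostly therapeutic), so a naive random 70/20/10 split can put all polyp
resections in one set.  Procedures are therefore clustered by their
per-class frame counts (k-means on z-scored 11-dimensional count vectors)
and each cluster is split proportionally, so every kind of procedure is
represented in train, test and validation alike.  One procedure belongs to
one patient; the no-patient-overlap invariant is still checked explicitly.

Training pools are balanced twice: within the positive class every
subclass is subsampled to the size of its smallest sibling (e.g. as many
washing as suction frames), and negatives are added at a fixed ratio —
2/3 negative for the classification task, 1/3 negative for the detection
task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import (
    MODEL_POSITIVE_LABELS,
    PhaseLabel,
    ProcedureTimeline,
)

__all__ = [
    "FEATURE_LABELS",
    "ProcedureFeatures",
    "features_from_timeline",
    "cluster_procedures",
    "SplitAssignment",
    "stratified_split",
    "BalancedSample",
    "subsample_training",
]

#: Feature order for the clustering: per-class annotated-frame counts.
FEATURE_LABELS: tuple[PhaseLabel, ...] = (
    PhaseLabel.AO,
    PhaseLabel.ICV,
    PhaseLabel.WASHING,
    PhaseLabel.SUCTION,
    PhaseLabel.INJECTION,
    PhaseLabel.OPTIMISING_POSITION,
    PhaseLabel.POLYPECTOMY,
    PhaseLabel.INSPECTING_RESECTION,
    PhaseLabel.FORCEP,
    PhaseLabel.NBI,
    PhaseLabel.NBI_NF,
)

SET_NAMES = ("train", "test", "val")
DEFAULT_RATIOS = (0.7, 0.2, 0.1)


@dataclass
class ProcedureFeatures:
    """Per-procedure frame counts for the 11 annotation classes."""

    procedure_id: str
    counts: np.ndarray  # shape (11,)
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(FEATURE_LABELS),):
            raise ValueError(
                f"expected {len(FEATURE_LABELS)} counts, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("frame counts must be non-negative")


def features_from_timeline(t: ProcedureTimeline) -> ProcedureFeatures:
    counts = np.zeros(len(FEATURE_LABELS), dtype=np.int64)
    index = {lab: i for i, lab in enumerate(FEATURE_LABELS)}
    for ann in t.annotations:
        for lab in ann.labels:
            counts[index[lab]] += 1
    return ProcedureFeatures(
        procedure_id=t.procedure_id, counts=counts, patient_id=t.patient_id
    )


def cluster_procedures(
    features: Sequence[ProcedureFeatures], k: int = 5, seed: int = 0
) -> np.ndarray:
    """K-means cluster labels over z-scored count vectors.

    Counts span orders of magnitude across classes, so each feature is
    standardised first; constant features are left at zero rather than
    dividing by a zero standard deviation.
    """
    n = len(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} procedures")
    x = np.stack([f.counts for f in features]).astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(z)


@dataclass
class SplitAssignment:
    """Total, disjoint procedure -> {train, test, val} mapping."""

    assignment: dict[str, str]
    seed: int
    k: int

    def members(self, set_name: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == set_name]


def _largest_remainder(m: int, ratios: Sequence[float]) -> list[int]:
    """Integer allocation of ``m`` items closest to ``ratios``.

    Floors the exact quotas, then hands the leftover items to the largest
    fractional remainders (ties broken toward the larger ratio, i.e. the
    earlier set in train/test/val order).
    """
    quotas = [m * r for r in ratios]
    alloc = [int(q) for q in quotas]
    remainder = m - sum(alloc)
    order = sorted(
        range(len(ratios)), key=lambda i: (quotas[i] - alloc[i], ratios[i]), reverse=True
    )
    for i in order[:remainder]:
        alloc[i] += 1
    return alloc


def stratified_split(
    features: Sequence[ProcedureFeatures],
    labels: Sequence[int],
    ratios: Sequence[float] = DEFAULT_RATIOS,
    seed: int = 0,
    k: Optional[int] = None,
) -> SplitAssignment:
    """70/20/10 split with every cluster proportionally represented.

    Within each cluster the procedures are shuffled (seeded) and allocated
    to train/test/val by largest-remainder rounding, so global proportions
    are within one procedure per cluster of the targets.  Raises if the
    resulting sets would share a patient.
    """
    if len(features) == 0:
        raise ValueError("no procedures to split")
    if len(features) != len(labels):
        raise ValueError("one cluster label per procedure required")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError("ratios must be three values summing to 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    assignment: dict[str, str] = {}
    for cluster in np.unique(labels):
        idx = np.flatnonzero(labels == cluster)
        rng.shuffle(idx)
        alloc = _largest_remainder(len(idx), ratios)
        cursor = 0
        for set_name, count in zip(SET_NAMES, alloc):
            for j in idx[cursor : cursor + count]:
                assignment[features[j].procedure_id] = set_name
            cursor += count
    # Patient-overlap check (one procedure per patient is the norm, but the
    # invariant is enforced, not assumed).
    patient_sets: dict[str, set[str]] = {}
    for f in features:
        if f.patient_id is None:
            continue
        patient_sets.setdefault(f.patient_id, set()).add(
            assignment[f.procedure_id]
        )
    overlapping = [p for p, s in patient_sets.items() if len(s) > 1]
    if overlapping:
        raise ValueError(f"patient(s) span multiple sets: {sorted(overlapping)}")
    return SplitAssignment(
        assignment=assignment,
        seed=seed,
        k=k if k is not None else len(np.unique(labels)),
    )


@dataclass
class BalancedSample:
    """Subclass-balanced positives plus ratio-matched negatives."""

    positives: dict[PhaseLabel, list[Hashable]]
    negatives: list[Hashable]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(len(v) for v in self.positives.values())


def subsample_training(
    frames: Sequence[tuple[Hashable, frozenset]],
    model: str,
    seed: int = 0,
    negative_ratio: float = 2.0,
) -> BalancedSample:
    """Balance a labelled frame pool for training one binary classifier.

    ``frames`` is a pool of ``(frame_ref, label_set)`` pairs.  Every
    subclass of the model's group is subsampled without replacement to the
    size of the smallest subclass; negatives (frames positive for no
    subclass of the model) are sampled to ``negative_ratio`` times the
    total positive count — 2.0 gives the classification-task mix of 2/3
    negative and 1/3 positive, 0.5 the detection-task mix of 1/3 negative
    and 2/3 positive.  If too few negatives exist, all are taken and a
    warning is recorded.
    """
    if model not in MODEL_POSITIVE_LABELS:
        raise ValueError(f"unknown model {model!r}")
    if negative_ratio < 0:
        raise ValueError("negative_ratio must be non-negative")
    rng = np.random.default_rng(seed)
    subclasses = sorted(MODEL_POSITIVE_LABELS[model])
    pools: dict[PhaseLabel, list[Hashable]] = {lab: [] for lab in subclasses}
    negatives_pool: list[Hashable] = []
    for ref, labels in frames:
        hit = False
        for lab in subclasses:
            if lab in labels:
                pools[lab].append(ref)
                hit = True
        if not hit:
            negatives_pool.append(ref)
    empty = [lab.value for lab in subclasses if not pools[lab]]
    if empty:
        raise ValueError(
            f"subclass(es) with no frames for model {model!r}: {empty}"
        )
    m = min(len(pools[lab]) for lab in subclasses)
    positives = {
        lab: [pools[lab][i] for i in rng.choice(len(pools[lab]), size=m, replace=False)]
        for lab in subclasses
    }
    n_pos = m * len(subclasses)
    n_neg_wanted = int(round(negative_ratio * n_pos))
    notes: list[str] = []
    if n_neg_wanted > len(negatives_pool):
        notes.append(
            f"wanted {n_neg_wanted} negatives but only "
            f"{len(negatives_pool)} available; taking all"
        )
        warnings.warn(notes[-1], stacklevel=2)
        negatives = list(negatives_pool)
        rng.shuffle(negatives)
    else:
        negatives = [
            negatives_pool[i]
            for i in rng.choice(len(negatives_pool), size=n_neg_wanted, replace=False)
        ]
    return BalancedSample(positives=positives, negatives=negatives, warnings=notes)
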