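"""Readers and writers for every on-disk format, plus the pipeline driver.

Formats (all plain text except the mask PNGs):

* timeline: ``<name>.csv`` with columns
  ``frame,labels,box_label,x0,y0,x1,y1,quality`` (labels semicolon-joined;
  one row per frame, extra rows for additional boxes) plus a sidecar
  ``<name>.json`` holding procedure metadata (ids, fps, frame count, frame
  size);
* score / prediction streams: ``frame,score`` and ``frame,pred`` CSV;
* detections: ``frame,label,x0,y0,x1,y1,confidence`` CSV;
* probability maps: one 16-bit grayscale PNG per channel
  (``<stem>.ao.png``, ``<stem>.icv.png``, ``<stem>.bg.png``), scaled to
  [0, 65535];
* split features and assignments as CSV; pipeline configuration as YAML.

Every writer produces files its own reader accepts (round-trip identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .cecum import DetectionFrame, ScoredBox, detect_cecum
from .core import (
    BoundingBox,
    FrameAnnotation,
    PhaseLabel,
    PredictionStream,
    ProcedureTimeline,
    ScoreStream,
    validate_timeline,
)
from .phases import FilterConfig, classify_stream, merge_or
from .split import FEATURE_LABELS, ProcedureFeatures, SplitAssignment
from .timer import WithdrawalEstimate, estimate_withdrawal

__all__ = [
    "read_timeline",
    "write_timeline",
    "read_scores",
    "write_scores",
    "read_predictions",
    "write_predictions",
    "read_detections",
    "write_detections",
    "read_mask",
    "write_mask",
    "read_features",
    "write_features",
    "read_split",
    "write_split",
    "PipelineConfig",
    "load_pipeline_config",
    "run_pipeline",
    "estimate_to_dict",
]

PathLike = Union[str, Path]

_TIMELINE_COLUMNS = ["frame", "labels", "box_label", "x0", "y0", "x1", "y1", "quality"]


class TimelineFormatError(ValueError):
    """Malformed annotation file; message names the offending line."""


def _sidecar(path: PathLike) -> Path:
    return Path(path).with_suffix(".json")


def write_timeline(t: ProcedureTimeline, path: PathLike) -> None:
    """Write the annotation CSV and its metadata sidecar JSON."""
    path = Path(path)
    rows = []
    for ann in t.annotations:
        labels = ";".join(lab.value for lab in sorted(ann.labels))
        if ann.boxes:
            for i, b in enumerate(ann.boxes):
                rows.append(
                    {
                        "frame": ann.frame_index,
                        "labels": labels if i == 0 else "",
                        "box_label": b.label.value,
                        "x0": b.x0,
                        "y0": b.y0,
                        "x1": b.x1,
                        "y1": b.y1,
                        "quality": (ann.quality or "") if i == 0 else "",
                    }
                )
        else:
            rows.append(
                {
                    "frame": ann.frame_index,
                    "labels": labels,
                    "box_label": "",
                    "x0": "",
                    "y0": "",
                    "x1": "",
                    "y1": "",
                    "quality": ann.quality or "",
                }
            )
    pd.DataFrame(rows, columns=_TIMELINE_COLUMNS).to_csv(path, index=False)
    meta = {
        "procedure_id": t.procedure_id,
        "patient_id": t.patient_id,
        "f": t.f,
        "ntotal": t.ntotal,
        "frame_size": list(t.frame_size) if t.frame_size else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_timeline(path: PathLike, validate: bool = True) -> ProcedureTimeline:
    """Read an annotation CSV plus sidecar; inverse of :func:`write_timeline`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TimelineFormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path, keep_default_na=False, dtype=str)
    except pd.errors.EmptyDataError:
        raise TimelineFormatError(f"{path}: empty annotation file") from None
    if df.empty:
        raise TimelineFormatError(f"{path}: annotation file has no rows")
    missing = set(_TIMELINE_COLUMNS) - set(df.columns)
    if missing:
        raise TimelineFormatError(f"{path}: missing column(s) {sorted(missing)}")

    frames: dict[int, dict] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            frame = int(row.frame)
        except ValueError:
            raise TimelineFormatError(
                f"{path}, line {row_no}: bad frame index {row.frame!r}"
            ) from None
        entry = frames.setdefault(frame, {"labels": set(), "boxes": [], "quality": None})
        if row.labels:
            for name in row.labels.split(";"):
                try:
                    entry["labels"].add(PhaseLabel(name))
                except ValueError:
                    raise TimelineFormatError(
                        f"{path}, line {row_no}: unknown label {name!r}"
                    ) from None
        if row.quality:
            entry["quality"] = row.quality
        if row.box_label:
            try:
                lab = PhaseLabel(row.box_label)
            except ValueError:
                raise TimelineFormatError(
                    f"{path}, line {row_no}: unknown box label {row.box_label!r}"
                ) from None
            try:
                coords = [int(getattr(row, c)) for c in ("x0", "y0", "x1", "y1")]
            except ValueError:
                raise TimelineFormatError(
                    f"{path}, line {row_no}: non-integer box coordinates"
                ) from None
            entry["boxes"].append(BoundingBox(lab, *coords))

    ntotal = int(meta["ntotal"])
    annotations = []
    for i in range(ntotal):
        entry = frames.get(i)
        if entry is None:
            annotations.append(FrameAnnotation(frame_index=i))
        else:
            annotations.append(
                FrameAnnotation(
                    frame_index=i,
                    labels=frozenset(entry["labels"]),
                    boxes=tuple(entry["boxes"]),
                    quality=entry["quality"],
                )
            )
    frame_size = meta.get("frame_size")
    t = ProcedureTimeline(
        procedure_id=meta["procedure_id"],
        patient_id=meta["patient_id"],
        annotations=annotations,
        f=float(meta["f"]),
        frame_size=tuple(frame_size) if frame_size else None,
    )
    if validate:
        problems = validate_timeline(t)
        if problems:
            raise TimelineFormatError(
                f"{path}: invalid timeline: " + "; ".join(problems[:5])
            )
    return t


def write_scores(s: ScoreStream, path: PathLike) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(s)), "score": s.scores}
    ).to_csv(path, index=False)


def read_scores(path: PathLike, model: str) -> ScoreStream:
    df = pd.read_csv(path)
    df = df.sort_values("frame")
    return ScoreStream(model=model, scores=df["score"].to_numpy(dtype=float))


def write_predictions(p: PredictionStream, path: PathLike) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(p)), "pred": p.preds.astype(int)}
    ).to_csv(path, index=False)


def read_predictions(path: PathLike, model: str) -> PredictionStream:
    df = pd.read_csv(path).sort_values("frame")
    return PredictionStream(model=model, preds=df["pred"].to_numpy(dtype=bool))


def write_detections(frames: Sequence[DetectionFrame], path: PathLike) -> None:
    rows = []
    for d in frames:
        for sb in d.boxes:
            rows.append(
                {
                    "frame": d.frame_index,
                    "label": sb.box.label.value,
                    "x0": sb.box.x0,
                    "y0": sb.box.y0,
                    "x1": sb.box.x1,
                    "y1": sb.box.y1,
                    "confidence": sb.confidence,
                }
            )
    pd.DataFrame(
        rows, columns=["frame", "label", "x0", "y0", "x1", "y1", "confidence"]
    ).to_csv(path, index=False)


def read_detections(path: PathLike) -> list[DetectionFrame]:
    """Read a detections CSV; frames without boxes are simply absent."""
    df = pd.read_csv(path)
    frames: dict[int, DetectionFrame] = {}
    for row in df.itertuples(index=False):
        d = frames.setdefault(int(row.frame), DetectionFrame(int(row.frame)))
        d.boxes.append(
            ScoredBox(
                box=BoundingBox(
                    PhaseLabel(row.label),
                    int(row.x0),
                    int(row.y0),
                    int(row.x1),
                    int(row.y1),
                ),
                confidence=float(row.confidence),
            )
        )
    return [frames[k] for k in sorted(frames)]


_MASK_SUFFIXES = (".ao.png", ".icv.png", ".bg.png")


def write_mask(prob_map: np.ndarray, stem: PathLike) -> list[Path]:
    """Write a (H, W, 3) probability map as three 16-bit grayscale PNGs."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 3 or prob_map.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) map, got {prob_map.shape}")
    stem = Path(stem)
    paths = []
    for c, suffix in enumerate(_MASK_SUFFIXES):
        path = stem.parent / (stem.name + suffix)
        iio.imwrite(path, np.round(prob_map[:, :, c] * 65535).astype(np.uint16))
        paths.append(path)
    return paths


def read_mask(stem: PathLike) -> np.ndarray:
    """Read the three per-channel PNGs back into a (H, W, 3) float map."""
    stem = Path(stem)
    channels = []
    for suffix in _MASK_SUFFIXES:
        path = stem.parent / (stem.name + suffix)
        if not path.exists():
            raise FileNotFoundError(f"missing mask channel {path}")
        channels.append(iio.imread(path).astype(float) / 65535.0)
    return np.stack(channels, axis=2)


def write_features(features: Sequence[ProcedureFeatures], path: PathLike) -> None:
    rows = []
    for f in features:
        row = {"procedure_id": f.procedure_id, "patient_id": f.patient_id or ""}
        row.update(
            {lab.value: int(c) for lab, c in zip(FEATURE_LABELS, f.counts)}
        )
        rows.append(row)
    cols = ["procedure_id", "patient_id"] + [lab.value for lab in FEATURE_LABELS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_features(path: PathLike) -> list[ProcedureFeatures]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        counts = [getattr(row, lab.value.replace("-", "_")) for lab in FEATURE_LABELS]
        out.append(
            ProcedureFeatures(
                procedure_id=str(row.procedure_id),
                counts=np.asarray(counts, dtype=np.int64),
                patient_id=str(row.patient_id) or None,
            )
        )
    return out


def write_split(split: SplitAssignment, path: PathLike) -> None:
    pd.DataFrame(
        {
            "procedure_id": list(split.assignment),
            "set": [split.assignment[p] for p in split.assignment],
        }
    ).to_csv(path, index=False)


def read_split(path: PathLike, seed: int = 0, k: int = 0) -> SplitAssignment:
    df = pd.read_csv(path)
    return SplitAssignment(
        assignment=dict(zip(df["procedure_id"].astype(str), df["set"])),
        seed=seed,
        k=k,
    )


@dataclass
class PipelineConfig:
    """Everything the end-to-end estimate needs, loadable from YAML."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    iou_min: float = 0.25
    min_area_fraction: float = 0.001
    f: float = 30.0
    split_k: int = 5
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0


def load_pipeline_config(path: PathLike) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    filt = FilterConfig()
    if "windows" in raw:
        filt.windows.update({k: int(v) for k, v in raw["windows"].items()})
    if "thresholds" in raw:
        filt.thresholds.update({k: float(v) for k, v in raw["thresholds"].items()})
    if "cut_point" in raw:
        filt.cut_point = float(raw["cut_point"])
    cfg = PipelineConfig(filter=filt)
    for key in ("iou_min", "min_area_fraction", "f", "split_k", "seed"):
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
    if "split_ratios" in raw:
        cfg.split_ratios = tuple(float(r) for r in raw["split_ratios"])
    return cfg


def estimate_to_dict(est: WithdrawalEstimate) -> dict:
    return {
        "valid": est.valid,
        "t_final_s": est.t_final_s,
        "t_final_mmss": est.t_final_mmss,
        "ntotal": est.ntotal,
        "f": est.f,
        "cecum_frame": est.cecum_frame,
        "n_insertion": est.n_insertion,
        "n_excluded_merged": est.n_excluded_merged,
        "n_cleaning": est.n_cleaning,
        "n_therapeutic": est.n_therapeutic,
        "n_forcep": est.n_forcep,
        "n_withdrawal": est.n_withdrawal,
    }


def run_pipeline(
    scores: dict[str, ScoreStream],
    cfg: PipelineConfig,
    detections: Optional[Sequence[DetectionFrame]] = None,
    cecum_frame: Optional[int] = None,
    log: Optional[list] = None,
) -> WithdrawalEstimate:
    """Drive trigger -> per-model classification -> OR merge -> timing.

    The cecum trigger comes either from a detection stream or directly as
    a frame index (e.g. ground truth).  Classification decisions are only
    consulted at/after the trigger; ``log``, when given, collects per-stage
    positive counts so the withdrawal-time bookkeeping is auditable.
    """
    lengths = {m: len(s) for m, s in scores.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"score streams disagree on frame count: {lengths}")
    ntotal = next(iter(lengths.values()))
    if detections is not None and cecum_frame is None:
        cecum_frame = detect_cecum(detections)
    per_model: dict[str, PredictionStream] = {}
    for m, s in scores.items():
        per_model[m] = classify_stream(
            s,
            n=cfg.filter.windows[m],
            theta=cfg.filter.thresholds[m],
            cut_point=cfg.filter.cut_point,
        )
        if log is not None:
            log.append(
                {
                    "stage": f"classified:{m}",
                    "positives": int(per_model[m].preds.sum()),
                }
            )
    merged = merge_or(*per_model.values())
    if log is not None:
        log.append({"stage": "merged", "positives": int(merged.preds.sum())})
        log.append({"stage": "trigger", "cecum_frame": cecum_frame})
    return estimate_withdrawal(
        ntotal=ntotal,
        cecum_frame=cecum_frame,
        merged=merged,
        f=cfg.f,
        cleaning=per_model.get("cleaning"),
        therapeutic=per_model.get("therapeutic"),
        forcep=per_model.get("forcep"),
    )
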