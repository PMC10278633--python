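from collections import deque

import numpy as np
import pytest

from colowt.cecum import (
    DetectionFrame,
    ScoredBox,
    detect_cecum,
    detection_metrics,
    iou,
    mask_to_boxes,
    match_boxes,
)
from colowt.core import BoundingBox, FrameAnnotation, PhaseLabel

from conftest import ao_box, icv_box, make_timeline


def flood_fill_components(binary):
    """Brute-force 4-connected component oracle: BFS, returns (area, bbox)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    out = []
    for sy in range(h):
        for sx in range(w):
            if not binary[sy, sx] or seen[sy, sx]:
                continue
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            area, y0, x0, y1, x1 = 0, sy, sx, sy, sx
            while q:
                y, x = q.popleft()
                area += 1
                y0, x0 = min(y0, y), min(x0, x)
                y1, x1 = max(y1, y), max(x1, x)
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            out.append((area, (x0, y0, x1 + 1, y1 + 1)))
    return out


def plant_map(shape, rects_by_channel, prob=0.9):
    """Probability map with given rectangles high in their class channel."""
    h, w = shape
    m = np.zeros((h, w, 3))
    m[:, :, 2] = 1.0
    for channel, rects in rects_by_channel.items():
        for (x0, y0, x1, y1) in rects:
            m[y0:y1, x0:x1, channel] = prob
            m[y0:y1, x0:x1, 2] = 1.0 - prob
    return m


class TestIoU:
    def test_identical_boxes(self):
        assert iou(ao_box(), ao_box()) == 1.0

    def test_disjoint_boxes(self):
        assert iou(ao_box(0, 0, 10, 10), ao_box(20, 20, 30, 30)) == 0.0

    def test_half_open_overlap_arithmetic(self):
        # [0,10)x[0,10) vs [5,15)x[0,10): inter 50, union 150
        a = ao_box(0, 0, 10, 10)
        b = ao_box(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.integers(0, 20, size=8)
            a = ao_box(x[0], x[1], x[0] + x[2] + 1, x[1] + x[3] + 1)
            b = ao_box(x[4], x[5], x[4] + x[6] + 1, x[5] + x[7] + 1)
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0
            assert (v == 1.0) == (a == b)


class TestMaskToBoxes:
    def test_pure_background_yields_nothing(self):
        m = plant_map((32, 32), {})
        assert mask_to_boxes(m).boxes == []

    def test_single_rectangle_recovered_exactly(self):
        m = plant_map((64, 64), {0: [(10, 5, 40, 25)]})
        (sb,) = mask_to_boxes(m).boxes
        assert (sb.box.x0, sb.box.y0, sb.box.x1, sb.box.y1) == (10, 5, 40, 25)
        assert sb.box.label is PhaseLabel.AO
        assert sb.confidence == pytest.approx(0.9)

    def test_small_component_suppressed(self):
        # 500 px and 3 px blobs; threshold 0.001 * 248*248 ~ 61.5 px
        m = plant_map((248, 248), {0: [(0, 0, 25, 20), (100, 100, 103, 101)]})
        boxes = mask_to_boxes(m, min_area_fraction=0.001).boxes
        assert len(boxes) == 1
        assert boxes[0].box.x1 == 25

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            mask_to_boxes(np.zeros((8, 8, 2)))

    def test_agrees_with_flood_fill_oracle_on_random_maps(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            m = np.zeros((32, 32, 3))
            m[:, :, 2] = 1.0
            for _ in range(rng.integers(1, 4)):
                x0, y0 = rng.integers(0, 28, size=2)
                x1 = x0 + rng.integers(1, 32 - x0 + 1)
                y1 = y0 + rng.integers(1, 32 - y0 + 1)
                ch = int(rng.integers(0, 2))
                m[y0:y1, x0:x1, :] = 0.0
                m[y0:y1, x0:x1, ch] = 1.0
            det = mask_to_boxes(m, min_area_fraction=0.0)
            for ch, lab in ((0, PhaseLabel.AO), (1, PhaseLabel.ICV)):
                binary = np.argmax(m, axis=2) == ch
                oracle = sorted(bbox for _, bbox in flood_fill_components(binary))
                mine = sorted(
                    (sb.box.x0, sb.box.y0, sb.box.x1, sb.box.y1)
                    for sb in det.boxes
                    if sb.box.label is lab
                )
                assert mine == oracle


class TestMatchBoxes:
    def frame(self, boxes):
        labels = frozenset(b.label for b in boxes)
        return FrameAnnotation(0, labels, tuple(boxes), "high" if boxes else None)

    def det(self, boxes, conf=0.9):
        return DetectionFrame(0, [ScoredBox(b, conf) for b in boxes])

    def test_identical_box_is_tp(self):
        out = match_boxes(self.det([ao_box()]), self.frame([ao_box()]))
        assert out[PhaseLabel.AO].tp == 1
        assert out[PhaseLabel.ICV].tn == 1

    def test_disjoint_boxes_give_fp_and_fn(self):
        out = match_boxes(
            self.det([ao_box(0, 0, 10, 10)]),
            self.frame([ao_box(40, 40, 50, 50)]),
        )
        assert out[PhaseLabel.AO].fp == 1 and out[PhaseLabel.AO].fn == 1

    def test_iou_threshold_boundary(self):
        pred = self.det([ao_box(0, 0, 10, 10)])
        gt = self.frame([ao_box(5, 0, 15, 10)])  # IoU exactly 1/3
        assert match_boxes(pred, gt, iou_min=1 / 3)[PhaseLabel.AO].tp == 1
        assert match_boxes(pred, gt, iou_min=0.34)[PhaseLabel.AO].tp == 0

    def test_invalid_iou_min_rejected(self):
        with pytest.raises(ValueError):
            match_boxes(self.det([]), self.frame([]), iou_min=1.5)


class TestDetectCecum:
    def test_no_boxes_anywhere(self):
        stream = [DetectionFrame(i) for i in range(10)]
        assert detect_cecum(stream) is None

    def test_earliest_of_either_landmark(self):
        stream = [DetectionFrame(i) for i in range(5000)]
        stream[4200].boxes.append(ScoredBox(icv_box(), 0.8))
        stream[4300].boxes.append(ScoredBox(ao_box(), 0.8))
        assert detect_cecum(stream) == 4200

    def test_simultaneous_landmarks(self):
        stream = [DetectionFrame(i) for i in range(4001)]
        stream[4000].boxes += [ScoredBox(ao_box(), 0.9), ScoredBox(icv_box(), 0.9)]
        assert detect_cecum(stream) == 4000

    def test_monotone_under_earlier_boxes(self):
        stream = [DetectionFrame(i) for i in range(100)]
        stream[50].boxes.append(ScoredBox(ao_box(), 0.9))
        before = detect_cecum(stream)
        stream[10].boxes.append(ScoredBox(icv_box(), 0.9))
        assert detect_cecum(stream) <= before


class TestDetectionMetrics:
    def make_procedure(self, detect_from_offset=0, drop_icv=False):
        t = make_timeline(
            [(20, set())],
            boxes_at={i: [ao_box(), icv_box()] for i in range(10, 15)},
        )
        detections = []
        for i in range(20):
            boxes = []
            if 10 + detect_from_offset <= i < 15:
                boxes.append(ScoredBox(ao_box(), 0.9))
                if not drop_icv:
                    boxes.append(ScoredBox(icv_box(), 0.9))
            detections.append(DetectionFrame(i, boxes))
        return detections, t

    def test_perfect_detector(self):
        report = detection_metrics([self.make_procedure()])
        for key in ("AO", "ICV", "both"):
            assert report.per_frame[key]["sensitivity"] == 1.0
            assert report.per_frame[key]["specificity"] == 1.0
            assert report.per_procedure_sensitivity[key] == 1.0
            assert report.mean_time_to_detection[key] == 0.0

    def test_delayed_detection_measures_lag(self):
        report = detection_metrics([self.make_procedure(detect_from_offset=2)])
        assert report.mean_time_to_detection["AO"] == 2.0

    def test_per_procedure_ratio(self):
        procedures = [
            self.make_procedure(),
            self.make_procedure(),
            self.make_procedure(drop_icv=True),
        ]
        report = detection_metrics(procedures)
        assert report.per_procedure_sensitivity["ICV"] == pytest.approx(2 / 3)
        assert report.per_procedure_sensitivity["both"] == 1.0

    def test_low_quality_frames_excluded(self):
        detections, t = self.make_procedure()
        ann = t.annotations[10]
        t.annotations[10] = FrameAnnotation(10, ann.labels, ann.boxes, "low")
        full = detection_metrics([(detections, t)], exclude_low_quality=False)
        trimmed = detection_metrics([(detections, t)], exclude_low_quality=True)
        assert trimmed.counts["AO"].tp == full.counts["AO"].tp - 1

    def test_empty_procedure_set_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics([])
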