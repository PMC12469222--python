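"""Tests of box IoU, NMS, the stand-in detector, cropping and AP."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundus_vcdr import (
    BBox,
    average_precision,
    box_from_mask,
    compute_vcdr,
    crop_square_roi,
    detect_od_bright,
    iou_boxes,
    match_detections,
    mean_ap,
    nms_filter,
    render_fundus,
    sample_spec,
)
from fundus_vcdr.synthetic import generate_samples


def lattice_iou(a: BBox, b: BBox) -> float:
    """Integer-grid cell-counting oracle for IoU of integer boxes."""
    cells_a = {(x, y) for x in range(int(a.x_min), int(a.x_max))
               for y in range(int(a.y_min), int(a.y_max))}
    cells_b = {(x, y) for x in range(int(b.x_min), int(b.x_max))
               for y in range(int(b.y_min), int(b.y_max))}
    return len(cells_a & cells_b) / len(cells_a | cells_b)


class TestIoU:
    def test_identity_and_disjoint(self):
        a = BBox(0, 0, 10, 10)
        assert iou_boxes(a, a) == 1.0
        assert iou_boxes(a, BBox(20, 20, 30, 30)) == 0.0
        assert iou_boxes(a, BBox(10, 0, 20, 10)) == 0.0  # half-open: touching

    def test_half_overlap_matches_lattice_oracle(self):
        a, b = BBox(0, 0, 10, 10), BBox(5, 0, 15, 10)
        assert iou_boxes(a, b) == pytest.approx(50 / 150)
        assert iou_boxes(a, b) == pytest.approx(lattice_iou(a, b))

    @given(st.lists(st.integers(0, 30), min_size=8, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_bounded(self, coords):
        x0, y0, w0, h0, x1, y1, w1, h1 = coords
        a = BBox(x0, y0, x0 + w0 + 1, y0 + h0 + 1)
        b = BBox(x1, y1, x1 + w1 + 1, y1 + h1 + 1)
        iou = iou_boxes(a, b)
        assert iou == iou_boxes(b, a)
        assert 0.0 <= iou <= 1.0
        assert iou == pytest.approx(lattice_iou(a, b))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BBox(5, 5, 5, 10)


class TestNMS:
    def test_duplicate_suppressed(self):
        """Two overlapping disc boxes collapse to the higher-confidence one."""
        a = BBox(0, 0, 10, 10, confidence=0.9)
        b = BBox(3, 0, 13, 10, confidence=0.6)  # IoU 7/13 > 0.3
        assert nms_filter([b, a]) == [a]

    def test_low_confidence_dropped(self):
        assert nms_filter([BBox(0, 0, 10, 10, confidence=0.4)]) == []

    def test_non_overlapping_all_kept_in_confidence_order(self):
        boxes = [BBox(0, 0, 10, 10, confidence=0.6),
                 BBox(50, 50, 60, 60, confidence=0.9),
                 BBox(100, 0, 110, 10, confidence=0.7)]
        kept = nms_filter(boxes)
        assert [b.confidence for b in kept] == [0.9, 0.7, 0.6]

    def test_output_pairwise_iou_bounded(self):
        rng = np.random.default_rng(0)
        boxes = [BBox(x, y, x + 20, y + 20, confidence=c)
                 for x, y, c in zip(rng.integers(0, 80, 30),
                                    rng.integers(0, 80, 30),
                                    rng.uniform(0.5, 1.0, 30))]
        kept = nms_filter(boxes, iou_thresh=0.3)
        assert set(kept) <= set(boxes)
        for a, b in itertools.combinations(kept, 2):
            assert iou_boxes(a, b) <= 0.3


class TestStandinDetector:
    def test_single_box_on_clean_sample(self):
        spec = sample_spec("normal", 21)
        spec = spec.__class__(**{**spec.__dict__, "noise_sd": 0.0})
        sample = render_fundus(spec)
        boxes = detect_od_bright(sample.image)
        assert len(boxes) == 1
        assert iou_boxes(boxes[0], box_from_mask(sample.mask)) >= 0.7

    def test_black_image_empty(self):
        assert detect_od_bright(np.zeros((64, 64, 3), np.uint8)) == []

    def test_recall_on_batch(self, sample_batch):
        hits = 0
        for s in sample_batch:
            boxes = detect_od_bright(s.image)
            gt = box_from_mask(s.mask)
            hits += bool(boxes) and iou_boxes(boxes[0], gt) > 0.5
        assert hits == len(sample_batch)


class TestCropSquareRoi:
    def test_arithmetic_oracle(self):
        """Expanded (30,50,250,280): side max(220,230)=230, centered crop."""
        image = np.zeros((640, 640, 3), np.uint8)
        mask = np.zeros((640, 640), np.uint8)
        crop, _, rec = crop_square_roi(image, mask, BBox(100, 120, 180, 210),
                                       margin=70)
        assert rec.side == 230
        assert (rec.window.x_min, rec.window.y_min) == (25, 50)
        assert (rec.window.x_max, rec.window.y_max) == (255, 280)
        assert crop.shape == (230, 230, 3)

    def test_zero_margin_square_box_identity(self):
        image = np.zeros((100, 100, 3), np.uint8)
        crop, _, rec = crop_square_roi(image, None, BBox(10, 20, 40, 50),
                                       margin=0)
        assert (rec.window.x_min, rec.window.y_min,
                rec.window.x_max, rec.window.y_max) == (10, 20, 40, 50)

    def test_edge_box_shifted_inside(self):
        image = np.zeros((200, 200, 3), np.uint8)
        crop, _, rec = crop_square_roi(image, None, BBox(0, 0, 30, 40),
                                       margin=30)
        assert crop.shape[0] == crop.shape[1] == rec.side
        assert rec.window.x_min >= 0 and rec.window.y_min >= 0
        assert rec.window.x_max <= 200 and rec.window.y_max <= 200

    def test_frame_too_small_raises(self):
        image = np.zeros((100, 100, 3), np.uint8)
        with pytest.raises(ValueError):
            crop_square_roi(image, None, BBox(10, 10, 90, 90), margin=70)

    def test_crop_preserves_vcdr_exactly(self):
        for s in generate_samples(2, 2, 55, image_size=640):
            box = detect_od_bright(s.image)[0]
            _, mask_crop, _ = crop_square_roi(s.image, s.mask, box, margin=70)
            assert compute_vcdr(mask_crop).vcdr == compute_vcdr(s.mask).vcdr


def brute_force_best_matching(preds, gts, iou_thresh):
    """Maximum-cardinality matching by exhaustive assignment enumeration."""
    best = 0
    options = list(range(len(gts))) + [None]
    for assign in itertools.product(options, repeat=len(preds)):
        used = [j for j in assign if j is not None]
        if len(used) != len(set(used)):
            continue  # a ground-truth box may be claimed at most once
        tp = sum(1 for i, j in enumerate(assign)
                 if j is not None and iou_boxes(preds[i], gts[j]) > iou_thresh)
        best = max(best, tp)
    return best


class TestMatching:
    def test_exact_hit(self):
        p, g = BBox(0, 0, 10, 10, confidence=0.9), BBox(0, 0, 10, 10)
        matches = match_detections([p], [g])
        assert matches == [(p, g)]

    def test_one_to_one_duplicate_is_fp(self):
        g = BBox(0, 0, 10, 10)
        p1 = BBox(0, 0, 10, 10, confidence=0.9)
        p2 = BBox(1, 0, 11, 10, confidence=0.8)
        matches = match_detections([p1, p2], [g])
        assert matches[0][1] is g and matches[1][1] is None

    def test_matches_exhaustive_optimum(self):
        """On a constructed 4-pred/3-gt scene greedy equals brute force."""
        gts = [BBox(0, 0, 20, 20), BBox(40, 0, 60, 20), BBox(80, 0, 100, 20)]
        preds = [BBox(1, 0, 21, 20, confidence=0.95),
                 BBox(41, 1, 61, 21, confidence=0.9),
                 BBox(82, 0, 102, 20, confidence=0.85),
                 BBox(200, 200, 220, 220, confidence=0.8)]
        matches = match_detections(preds, gts, iou_thresh=0.5)
        tp = sum(1 for _, g in matches if g is not None)
        assert tp == brute_force_best_matching(preds, gts, 0.5) == 3


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        g = BBox(0, 0, 10, 10)
        assert average_precision([BBox(0, 0, 10, 10, confidence=0.9)], [g]) == 1.0

    def test_no_predictions(self):
        assert average_precision([], [BBox(0, 0, 10, 10)]) == 0.0

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError):
            average_precision([BBox(0, 0, 10, 10, confidence=0.9)], [])

    @staticmethod
    def toy_scene():
        gts = [BBox(0, 0, 10, 10), BBox(20, 0, 30, 10), BBox(40, 0, 50, 10)]
        preds = [
            BBox(0, 0, 10, 10, confidence=0.95),       # TP on gt1
            BBox(100, 100, 110, 110, confidence=0.9),  # FP
            BBox(20, 0, 30, 10, confidence=0.8),       # TP on gt2
            BBox(1, 1, 11, 11, confidence=0.7),        # duplicate -> FP
            BBox(40, 0, 50, 10, confidence=0.6),       # TP on gt3
        ]
        return preds, gts

    def test_toy_scene_matches_hand_enumeration(self):
        """TP flags (1,0,1,0,1): interpolated precision is 1 up to recall
        1/3, 2/3 up to 2/3, 0.6 up to 1 -> AP = (34 + 33*2/3 + 34*0.6)/101."""
        preds, gts = self.toy_scene()
        expected = (34 * 1.0 + 33 * (2 / 3) + 34 * 0.6) / 101
        assert average_precision(preds, gts, 0.5) == pytest.approx(expected)

    def test_high_confidence_fp_never_raises_ap(self):
        preds, gts = self.toy_scene()
        base = average_precision(preds, gts, 0.5)
        spiked = [BBox(300, 300, 310, 310, confidence=0.99)] + preds
        assert average_precision(spiked, gts, 0.5) <= base

    def test_map_single_class_equals_ap_mean(self):
        preds, gts = self.toy_scene()
        thresholds = np.arange(0.50, 0.951, 0.05)
        expected = np.mean([average_precision(preds, gts, t) for t in thresholds])
        assert mean_ap(preds, gts) == pytest.approx(expected)
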