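"""Evaluation stack: matching, precision/recall, AP, pixel metrics."""

import itertools

import numpy as np
import pytest

from weednet.annotations import AnnotationSet, ImageRecord, InstanceAnnotation
from weednet.detections import Detection, DetectionList
from weednet.metrics import (
    EvalCounts,
    average_precision,
    box_iou,
    ground_truth_detections,
    map50,
    map50_95,
    mask_iou,
    match_and_count,
    pixel_metrics,
    precision_recall,
    rasterize_polygon,
    read_detections_json,
    write_detections_json,
)


def rect(x1, y1, x2, y2):
    return np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]], float)


def det(image_id, cls, conf, box, grid=None):
    mask = None
    if grid is not None:
        mask = rasterize_polygon(rect(*box), *grid)
    return Detection(image_id=image_id, class_id=cls, confidence=conf,
                     box=np.asarray(box, float), mask=mask)


def truth_set(boxes_by_class, size=64, classes=("a", "b")):
    instances = [
        InstanceAnnotation(0, classes[c], rect(*b)) for c, bs in boxes_by_class.items() for b in bs
    ]
    return AnnotationSet(
        images=[ImageRecord(image_id=0, width=size, height=size)],
        instances=instances,
        classes=classes,
    )


class TestIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_overlap_area_arithmetic(self):
        assert box_iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_mask_iou_empty_union_is_zero(self):
        z = np.zeros((4, 4), bool)
        assert mask_iou(z, z) == 0.0

    def test_mask_iou_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestMatching:
    def test_perfect_duplicates_give_no_errors(self):
        truth = truth_set({0: [(5, 5, 20, 20)], 1: [(30, 30, 50, 50)]})
        preds = ground_truth_detections(truth)
        counts = match_and_count(preds, truth, 0.5, kind="box")
        tp, fp, fn = counts.totals()
        assert (tp, fp, fn) == (2, 0, 0)

    def test_no_predictions_gives_all_false_negatives(self):
        truth = truth_set({0: [(5, 5, 20, 20), (30, 5, 45, 20)]})
        counts = match_and_count(DetectionList(), truth, 0.5, kind="box")
        tp, fp, fn = counts.totals()
        assert (tp, fp, fn) == (0, 0, 2)

    def test_threshold_outside_unit_interval_rejected(self):
        truth = truth_set({0: [(5, 5, 20, 20)]})
        with pytest.raises(ValueError):
            match_and_count(DetectionList(), truth, 1.5)

    def test_constructed_ious_match_exhaustive_assignment(self):
        # 3 truths, 4 scored predictions at t = 0.5
        truth = truth_set({0: [(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10)]})
        preds = DetectionList([
            det(0, 0, 0.9, (0, 0, 10, 10)),    # perfect on gt1
            det(0, 0, 0.8, (21, 0, 31, 10)),   # strong on gt2
            det(0, 0, 0.7, (0, 0, 9, 10)),     # duplicate of gt1 -> FP
            det(0, 0, 0.6, (40, 5, 50, 15)),   # IoU 1/3 with gt3 -> FP
        ])
        counts = match_and_count(preds, truth, 0.5, kind="box")
        tp, fp, fn = counts.totals()
        assert (tp, fp, fn) == (2, 2, 1)
        assert _exhaustive_tp(preds, truth, 0.5) == tp


def _exhaustive_tp(preds, truth, t):
    """Maximum-cardinality matching by brute-force enumeration."""
    best = 0
    gts = [(truth.class_index(i.class_label), i.bbox) for i in truth.instances]
    ds = [(d.class_id, tuple(d.box)) for d in preds]
    for perm in itertools.permutations(range(len(gts)), min(len(ds), len(gts))):
        tp = sum(
            1
            for d_i, g_i in zip(range(len(ds)), perm)
            if ds[d_i][0] == gts[g_i][0] and box_iou(ds[d_i][1], gts[g_i][1]) >= t
        )
        best = max(best, tp)
    return best


class TestPrecisionRecall:
    def test_formula_arithmetic(self):
        c = EvalCounts(tp={"a": 8}, fp={"a": 2}, fn={"a": 2})
        assert precision_recall(c) == (0.8, 0.8)

    def test_zero_over_zero_convention(self):
        c = EvalCounts(tp={"a": 0}, fp={"a": 0}, fn={"a": 5})
        assert precision_recall(c) == (0.0, 0.0)

    def test_perfect_counts(self):
        c = EvalCounts(tp={"a": 4}, fp={"a": 0}, fn={"a": 0})
        assert precision_recall(c) == (1.0, 1.0)


def ap_101_oracle(flags, n_truth):
    """Brute-force PR integration at 101 recall points."""
    tp = np.cumsum(flags)
    fp = np.cumsum(~np.asarray(flags, bool))
    recall = tp / n_truth
    precision = tp / np.maximum(tp + fp, 1)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        candidates = precision[recall >= r]
        total += candidates.max() if len(candidates) else 0.0
    return total / 101


class TestAveragePrecision:
    def test_perfect_ranking_gives_ap_one(self):
        truth = truth_set({0: [(5, 5, 20, 20), (30, 30, 50, 50)]})
        preds = ground_truth_detections(truth)
        assert average_precision(preds, truth, "a", 0.5, kind="box") == pytest.approx(1.0)

    def test_zero_true_positives_give_ap_zero(self):
        truth = truth_set({0: [(5, 5, 20, 20)]})
        preds = DetectionList([det(0, 0, 0.9, (40, 40, 60, 60))])
        assert average_precision(preds, truth, "a", 0.5, kind="box") == 0.0

    def test_ranked_outcome_sequence_matches_101_point_oracle(self):
        # 3 truths, ranked outcomes (TP, FP, TP, TP)
        truth = truth_set({0: [(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10)]})
        preds = DetectionList([
            det(0, 0, 0.9, (0, 0, 10, 10)),
            det(0, 0, 0.8, (0, 20, 10, 30)),
            det(0, 0, 0.7, (20, 0, 30, 10)),
            det(0, 0, 0.6, (40, 0, 50, 10)),
        ])
        ap = average_precision(preds, truth, "a", 0.5, kind="box")
        assert ap == pytest.approx(ap_101_oracle([1, 0, 1, 1], 3), abs=1e-9)

    def test_ap_invariant_to_monotone_confidence_rescaling(self):
        truth = truth_set({0: [(0, 0, 10, 10), (20, 0, 30, 10)]})
        preds = DetectionList([
            det(0, 0, 0.9, (0, 0, 10, 10)),
            det(0, 0, 0.5, (0, 20, 10, 30)),
            det(0, 0, 0.3, (20, 0, 30, 10)),
        ])
        ap1 = average_precision(preds, truth, "a", 0.5, kind="box")
        squashed = DetectionList([
            Detection(d.image_id, d.class_id, d.confidence ** 3 * 0.5, d.box, d.mask)
            for d in preds
        ])
        ap2 = average_precision(squashed, truth, "a", 0.5, kind="box")
        assert ap1 == pytest.approx(ap2, abs=1e-12)

    def test_class_absent_from_truth_is_skipped(self):
        truth = truth_set({0: [(5, 5, 20, 20)]})  # class 'b' has no truth
        preds = ground_truth_detections(truth)
        assert average_precision(preds, truth, "b", 0.5, kind="box") is None
        assert map50(preds, truth, kind="box") == pytest.approx(1.0)

    def test_map50_95_never_exceeds_map50(self, rng):
        for trial in range(10):
            truth = truth_set({
                0: [tuple(sorted(rng.uniform(0, 60, 2))) + (0, 10) for _ in range(2)]
            })
            truth = truth_set({0: [(5, 5, 25, 22), (30, 30, 52, 50)]})
            preds = DetectionList([
                det(0, 0, float(c), tuple(b))
                for c, b in zip(
                    rng.uniform(0.1, 1, 3),
                    [(4, 6, 25, 23), (31, 28, 50, 50), (1, 40, 12, 55)],
                )
            ])
            assert map50_95(preds, truth, kind="box") <= map50(preds, truth, kind="box") + 1e-12


class TestPixelMetrics:
    def test_identical_prediction_gives_ones(self, tiny_scene_dataset):
        dataset, _ = tiny_scene_dataset
        preds = ground_truth_detections(dataset)
        macc, miou, _ = pixel_metrics(preds, dataset)
        assert macc == 1.0 and miou == 1.0

    def test_formula_arithmetic_on_fixed_tallies(self):
        # two classes with pixel tallies TP=(8,9), FP=(1,2), FN=(2,1);
        # each truth rectangle rasterizes to exactly 10 pixels (2 rows x 5)
        grid = 16
        truth = truth_set(
            {0: [(0, 0, 4, 1)], 1: [(0, 3, 4, 4)]}, size=grid
        )
        tgrid0 = rasterize_polygon(rect(0, 0, 4, 1), grid, grid)
        tgrid1 = rasterize_polygon(rect(0, 3, 4, 4), grid, grid)
        tp0, fp0, fn0 = 8, 1, 2
        m0 = np.zeros((grid, grid), bool)
        idx0 = np.argwhere(tgrid0)
        m0[tuple(idx0[:tp0].T)] = True
        free = np.argwhere(~(tgrid0 | tgrid1))
        m0[tuple(free[:fp0].T)] = True
        tp1, fp1, fn1 = 9, 2, 1
        m1 = np.zeros((grid, grid), bool)
        idx1 = np.argwhere(tgrid1)
        m1[tuple(idx1[:tp1].T)] = True
        m1[tuple(free[fp0 : fp0 + fp1].T)] = True
        assert tgrid0.sum() == tp0 + fn0 and tgrid1.sum() == tp1 + fn1
        preds = DetectionList([
            Detection(0, 0, 0.9, np.array([0, 0, grid, grid], float), m0),
            Detection(0, 1, 0.8, np.array([0, 0, grid, grid], float), m1),
        ])
        macc, miou, _ = pixel_metrics(preds, truth)
        assert macc == pytest.approx((8 / 10 + 9 / 10) / 2)
        assert miou == pytest.approx((8 / 11 + 9 / 12) / 2)

    def test_empty_prediction_nonempty_truth_gives_zero(self):
        truth = truth_set({0: [(5, 5, 20, 20)]})
        macc, miou, _ = pixel_metrics(DetectionList(), truth)
        assert macc == 0.0 and miou == 0.0

    def test_miou_never_exceeds_macc(self, rng):
        for trial in range(20):
            truth = truth_set({0: [(2, 2, 30, 30)], 1: [(35, 35, 60, 60)]})
            preds = DetectionList([
                det(0, int(rng.integers(2)), float(rng.uniform(0.2, 1)),
                    tuple(np.sort(rng.uniform(0, 64, 2))) + (5, 30), grid=(64, 64))
                for _ in range(3)
            ])
            macc, miou, _ = pixel_metrics(preds, truth)
            assert 0.0 <= miou <= macc <= 1.0


class TestDetectionsJson:
    def test_roundtrip_with_rle_masks(self, tmp_path):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 3:7] = True
        preds = DetectionList([
            Detection(0, 1, 0.75, np.array([3, 2, 7, 5], float), mask),
            Detection(1, 0, 0.5, np.array([0, 0, 4, 4], float), None),
        ])
        write_detections_json(preds, tmp_path / "dets.json")
        back = read_detections_json(tmp_path / "dets.json")
        assert len(back) == 2
        assert np.array_equal(back.detections[0].mask, mask)
        assert back.detections[0].class_id == 1
        assert np.allclose(back.detections[1].box, [0, 0, 4, 4])
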