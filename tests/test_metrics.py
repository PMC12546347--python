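"""Segmentation/detection/counting metric identities and invariants."""

import numpy as np
import pytest

from leafcount.geometry import BBox, Detection
from leafcount.metrics import (
    CountReport,
    ZeroGroundTruthError,
    average_precision,
    classify_scale,
    count_rmse,
    dataset_stats,
    match_detections,
    mean_average_precision,
    seg_metrics,
)

from conftest import random_boxes


class TestSegMetrics:
    def test_identical_masks_score_one(self, rng):
        m = rng.random((32, 32)) > 0.5
        assert seg_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_total_disagreement_scores_zero(self):
        pred = np.zeros((10, 10), dtype=bool)
        gt = np.zeros((10, 10), dtype=bool)
        pred[:, :5] = True
        gt[:, 5:] = True
        assert seg_metrics(pred, gt) == (0.0, 0.0, 0.0)

    def test_empty_pair_convention_is_perfect_agreement(self):
        e = np.zeros((5, 5), dtype=bool)
        pa, iou, f1 = seg_metrics(e, e)
        assert (pa, iou, f1) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_pixel_count_oracle(self, case):
        r = np.random.default_rng(100 + case)
        pred = r.random((32, 32)) > 0.4
        gt = r.random((32, 32)) > 0.6
        pa, iou, f1 = seg_metrics(pred, gt)
        tp = fp = fn = tn = 0
        for i in range(32):
            for j in range(32):
                tp += pred[i, j] and gt[i, j]
                fp += pred[i, j] and not gt[i, j]
                fn += gt[i, j] and not pred[i, j]
                tn += not pred[i, j] and not gt[i, j]
        assert pa == pytest.approx((tp + tn) / 1024)
        assert iou == pytest.approx(tp / (tp + fp + fn))
        assert f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
        assert f1 >= iou  # Dice never below Jaccard

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((3, 3)), np.zeros((4, 4)))


def oracle_match(dets, gts, thr):
    """Exhaustive confidence-ordered single-use assignment; returns TP count."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    used, tp = set(), 0
    for i in order:
        best, best_iou = None, thr - 1e-12
        for j, g in enumerate(gts):
            if j in used or g.label != dets[i].label:
                continue
            iou = dets[i].box.iou(g.box)
            if iou > best_iou:
                best, best_iou = j, iou
        if best is not None and best_iou >= thr:
            used.add(best)
            tp += 1
    return tp


class TestMatchDetections:
    def test_perfect_overlap_is_true_positive(self):
        g = [Detection(BBox(0, 0, 10, 10), "adult", 1.0)]
        d = [Detection(BBox(0, 0, 10, 10), "adult", 0.9)]
        m = match_detections(d, g, 0.5)
        assert (m.tp["adult"], m.fp["adult"], m.fn["adult"]) == (1, 0, 0)

    def test_each_ground_truth_matches_once(self):
        g = [Detection(BBox(0, 0, 10, 10), "adult", 1.0)]
        d = [
            Detection(BBox(0, 0, 10, 10), "adult", 0.9),
            Detection(BBox(1, 0, 11, 10), "adult", 0.8),
        ]
        m = match_detections(d, g, 0.5)
        assert (m.tp["adult"], m.fp["adult"]) == (1, 1)
        assert m.flags["adult"] == [(0.9, True), (0.8, False)]

    @pytest.mark.parametrize("case", range(30))
    def test_tp_count_matches_exhaustive_oracle(self, case):
        r = np.random.default_rng(7000 + case)
        dets = random_boxes(r, int(r.integers(0, 10)))
        gts = random_boxes(r, int(r.integers(0, 10)))
        m = match_detections(dets, gts, 0.5)
        assert sum(m.tp.values()) == oracle_match(dets, gts, 0.5)

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], -0.1)


def _match_from_flags(flags, n_gt, label="adult"):
    from leafcount.metrics import MatchResult

    m = MatchResult()
    m.n_gt[label] = n_gt
    m.flags[label] = flags
    return m


class TestAveragePrecision:
    def test_single_true_positive_gives_ap_one(self):
        m = _match_from_flags([(0.9, True)], 1)
        assert average_precision([m], "adult") == 1.0

    def test_worked_three_ground_truth_example(self):
        # flags in confidence order [TP, FP, TP] over 3 ground truths:
        # interpolated area = 1 * 1/3 + 2/3 * 1/3 = 5/9
        m = _match_from_flags([(0.9, True), (0.8, False), (0.7, True)], 3)
        assert average_precision([m], "adult") == pytest.approx(5 / 9)

    def test_zero_ground_truth_is_signaled(self):
        m = _match_from_flags([(0.9, False)], 0)
        with pytest.raises(ZeroGroundTruthError):
            average_precision([m], "adult")

    @pytest.mark.parametrize("case", range(15))
    def test_matches_dense_integration_oracle(self, case):
        r = np.random.default_rng(300 + case)
        n_gt = int(r.integers(1, 8))
        n_det = int(r.integers(1, 12))
        flags, tp_budget = [], n_gt
        for _ in range(n_det):
            is_tp = bool(r.random() < 0.5) and tp_budget > 0
            tp_budget -= is_tp
            flags.append((float(np.round(r.uniform(0.05, 1), 6)), is_tp))
        m = _match_from_flags(flags, n_gt)
        ap = average_precision([m], "adult")
        # oracle: evaluate the interpolated precision on a dense recall grid
        fl = sorted(flags, key=lambda t: -t[0])
        tp = np.cumsum([f[1] for f in fl])
        fp = np.cumsum([not f[1] for f in fl])
        rec = tp / n_gt
        prec = tp / (tp + fp)
        grid = np.linspace(1e-9, 1.0, 200001)
        interp = np.zeros_like(grid)
        for g_i, r_val in enumerate(grid):
            candidates = prec[rec >= r_val - 1e-12]
            interp[g_i] = candidates.max() if len(candidates) else 0.0
        oracle = float(np.trapezoid(interp, grid))
        assert ap == pytest.approx(oracle, abs=2e-4)

    def test_false_positive_never_raises_ap(self):
        base = [(0.9, True), (0.7, True)]
        for conf in (0.95, 0.8, 0.5):
            with_fp = sorted(base + [(conf, False)], key=lambda t: -t[0])
            ap0 = average_precision([_match_from_flags(base, 3)], "adult")
            ap1 = average_precision([_match_from_flags(with_fp, 3)], "adult")
            assert ap1 <= ap0

    def test_invariant_under_joint_duplication(self):
        flags = [(0.9, True), (0.8, False), (0.7, True)]
        single = average_precision([_match_from_flags(flags, 3)], "adult")
        double = average_precision(
            [_match_from_flags(flags, 3), _match_from_flags(flags, 3)], "adult"
        )
        assert double == pytest.approx(single)

    def test_map_is_mean_over_classes(self):
        ma = _match_from_flags([(0.9, True)], 1, "adult")
        mn = _match_from_flags([(0.9, False)], 1, "nymph")
        m = ma
        m.n_gt.update(mn.n_gt)
        m.flags.update(mn.flags)
        assert mean_average_precision([m], ["adult", "nymph"]) == pytest.approx(0.5)


class TestCountRmse:
    def test_closed_form_example(self):
        reports = [
            CountReport({"adult": 3}, {"adult": 1}),
            CountReport({"adult": 5}, {"adult": 5}),
        ]
        out = count_rmse(reports)
        assert out["overall"] == pytest.approx(np.sqrt(2))
        assert out["adult"] == pytest.approx(np.sqrt(2))

    def test_perfect_counts_give_zero(self):
        reports = [CountReport({"adult": 4, "nymph": 2}, {"adult": 4, "nymph": 2})]
        assert count_rmse(reports)["overall"] == 0.0

    def test_matches_direct_formula(self, rng):
        pred = rng.integers(0, 30, 50)
        true = rng.integers(0, 30, 50)
        reports = [
            CountReport({"adult": int(p)}, {"adult": int(t)}) for p, t in zip(pred, true)
        ]
        expected = float(np.sqrt(np.mean((pred - true) ** 2)))
        assert count_rmse(reports)["adult"] == pytest.approx(expected)

    def test_constant_shift_bounds_rmse_below(self):
        c = 3
        reports = [CountReport({"adult": 7 + c}, {"adult": 7}) for _ in range(10)]
        assert count_rmse(reports)["overall"] >= c

    def test_rejects_empty_and_truthless_input(self):
        with pytest.raises(ValueError):
            count_rmse([])
        with pytest.raises(ValueError):
            count_rmse([CountReport({"adult": 1})])


class TestClassifyScale:
    @pytest.mark.parametrize(
        "w,h,expected",
        [
            (24, 25, "small"),  # median adult box
            (19, 19, "small"),  # median nymph box
            (31, 33, "small"),  # area 1023 < 32*32
            (32, 32, "medium"),  # closed lower boundary
            (96, 96, "medium"),  # closed upper boundary
            (100, 100, "large"),
        ],
    )
    def test_area_banding(self, w, h, expected):
        assert classify_scale(w, h) == expected

    def test_rejects_non_positive_dims(self):
        with pytest.raises(ValueError):
            classify_scale(0, 10)


class TestDatasetStats:
    def test_single_image_arithmetic(self):
        anns = [
            [
                Detection(BBox(0, 0, 10, 10), "adult", 1.0),
                Detection(BBox(20, 20, 40, 40), "adult", 1.0),
            ]
        ]
        s = dataset_stats(anns)["classes"]["adult"]
        assert s["median_width"] == 15 and s["median_height"] == 15
        assert s["count_mean"] == 2 and s["count_sd"] == 0
        assert s["scale_fractions"]["small"] == 1.0

    def test_empty_annotations_are_degenerate(self):
        s = dataset_stats([[], [], []])
        assert s["n_images"] == 3 and s["classes"] == {}
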