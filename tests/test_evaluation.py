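import itertools

import numpy as np
import pytest

from stomakit.detection import DetectionBox
from stomakit.evaluation import (compute_metrics, confidence_curve, f1_score,
                                 iou, mask_agreement, match_detections)
from stomakit.measure import mask_from_polygons


def pred(x, y, w, h, conf):
    return DetectionBox(image_id="t", bbox=(x, y, w, h), confidence=conf)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0

    def test_half_shifted_squares(self):
        assert iou((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = (0, 0, 7, 9), (3, 2, 8, 4)
        assert iou(a, b) == iou(b, a)


class TestMatching:
    def test_exact_predictions_all_pair(self):
        gt = [(0, 0, 10, 10), (30, 0, 10, 10)]
        preds = [pred(*g, 0.9) for g in gt]
        m = match_detections(gt, preds, 0.5)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0

    def test_partial_coverage_with_spurious(self):
        rng = np.random.default_rng(3)
        gt = [(60 * i, 60 * j, 20, 20) for i in range(5) for j in range(2)]
        preds = [pred(*gt[k], 0.9) for k in range(8)]
        preds += [pred(1000, 1000 + 50 * k, 10, 10, 0.8) for k in range(2)]
        m = match_detections(gt, preds, 0.5)
        assert (m.tp, m.fp, m.fn) == (8, 2, 2)

    def test_highest_confidence_claims_the_gt(self):
        gt = [(0, 0, 10, 10)]
        a = pred(0, 1, 10, 10, 0.8)
        b = pred(1, 0, 10, 10, 0.7)
        m = match_detections(gt, [b, a], 0.5)
        assert m.pairs[0][1] == 1  # index of the conf-0.8 prediction
        assert m.false_positives == [0]

    def test_partition_identities(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_gt, n_pred = rng.integers(0, 7, size=2)
            gt = [(rng.uniform(0, 80), rng.uniform(0, 80), 10, 10)
                  for _ in range(n_gt)]
            preds = [pred(rng.uniform(0, 80), rng.uniform(0, 80), 10, 10,
                          rng.uniform(0, 1)) for _ in range(n_pred)]
            m = match_detections(gt, preds, 0.5)
            assert m.tp + m.fp == n_pred
            assert m.tp + m.fn == n_gt
            paired_gt = [g for g, _, _ in m.pairs]
            paired_pred = [p for _, p, _ in m.pairs]
            assert len(set(paired_gt)) == len(paired_gt)
            assert len(set(paired_pred)) == len(paired_pred)
            assert all(v >= 0.5 for _, _, v in m.pairs)

    def test_metrics_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        gt = [(rng.uniform(0, 100), rng.uniform(0, 100), 12, 12) for _ in range(6)]
        preds = [pred(g[0] + rng.uniform(-2, 2), g[1] + rng.uniform(-2, 2),
                      12, 12, c) for g, c in zip(gt, np.linspace(0.3, 0.9, 6))]
        ref = compute_metrics(match_detections(gt, preds, 0.5))
        for perm in itertools.islice(itertools.permutations(preds), 0, 24, 5):
            m = compute_metrics(match_detections(gt, list(perm), 0.5))
            assert (m.tp, m.fp, m.fn) == (ref.tp, ref.fp, ref.fn)


def brute_force_max_matching(gt, preds, thr):
    """Maximum-cardinality IoU-feasible matching by exhaustive search."""
    feasible = [
        [j for j in range(len(gt)) if iou(p.bbox, gt[j]) >= thr] for p in preds
    ]

    def best(i, used):
        if i == len(preds):
            return 0
        score = best(i + 1, used)
        for j in feasible[i]:
            if j not in used:
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())


class TestGreedyVsBruteForce:
    def test_greedy_is_near_optimal_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n_gt, n_pred = rng.integers(0, 7, size=2)
            gt = [(rng.uniform(0, 60), rng.uniform(0, 60),
                   rng.uniform(8, 16), rng.uniform(8, 16)) for _ in range(n_gt)]
            preds = [pred(rng.uniform(0, 60), rng.uniform(0, 60),
                          rng.uniform(8, 16), rng.uniform(8, 16),
                          rng.uniform(0, 1)) for _ in range(n_pred)]
            m = match_detections(gt, preds, 0.3)
            opt = brute_force_max_matching(gt, preds, 0.3)
            assert opt - 1 <= m.tp <= opt


class TestMetrics:
    @pytest.mark.parametrize("p,r,f1_printed", [
        (0.993, 0.998, 0.995),
        (0.898, 0.917, 0.907),
        (0.977, 0.815, 0.889),
        (0.868, 0.926, 0.896),
        (0.836, 0.913, 0.873),
    ])
    def test_f1_is_harmonic_mean(self, p, r, f1_printed):
        assert f1_score(p, r) == pytest.approx(f1_printed, abs=5e-4)

    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 1.0])
    def test_equal_precision_recall_fixed_point(self, x):
        assert f1_score(x, x) == pytest.approx(x)

    def test_counts_to_metrics(self):
        gt = [(0, 0, 10, 10), (40, 0, 10, 10), (80, 0, 10, 10)]
        preds = [pred(0, 0, 10, 10, 0.9), pred(40, 0, 10, 10, 0.8),
                 pred(200, 200, 10, 10, 0.7)]
        m = compute_metrics(match_detections(gt, preds, 0.5))
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_zero_predictions_convention(self):
        m = compute_metrics(match_detections([(0, 0, 5, 5)], [], 0.5))
        assert m.precision == 1.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_zero_gt_convention(self):
        m = compute_metrics(match_detections([], [pred(0, 0, 5, 5, 0.9)], 0.5))
        assert m.recall == 1.0 and m.precision == 0.0

    def test_empty_image_perfect(self):
        m = compute_metrics(match_detections([], [], 0.5))
        assert m.precision == 1.0 and m.recall == 1.0


class TestConfidenceCurve:
    def test_constant_when_all_confidences_are_one(self):
        gt = [(0, 0, 10, 10)]
        preds = [pred(0, 0, 10, 10, 1.0)]
        curve = confidence_curve(gt, preds, 0.5, grid_size=11)
        assert np.all(curve.f1 == curve.f1[0])

    def test_recall_zero_above_max_confidence(self):
        gt = [(0, 0, 10, 10)]
        preds = [pred(0, 0, 10, 10, 0.55)]
        curve = confidence_curve(gt, preds, 0.5, grid_size=101)
        above = curve.thresholds > 0.55
        assert np.all(curve.recall[above] == 0.0)

    def test_recall_non_increasing(self):
        rng = np.random.default_rng(7)
        gt = [(30 * i, 30 * j, 12, 12) for i in range(4) for j in range(4)]
        preds = [pred(g[0] + rng.uniform(-3, 3), g[1] + rng.uniform(-3, 3),
                      12, 12, rng.uniform(0.1, 0.99)) for g in gt[:12]]
        preds += [pred(rng.uniform(200, 300), rng.uniform(200, 300), 12, 12,
                       rng.uniform(0.1, 0.99)) for _ in range(4)]
        curve = confidence_curve(gt, preds, 0.5)
        assert np.all(np.diff(curve.recall) <= 1e-12)

    def test_best_threshold_maximizes_f1(self):
        gt = [(0, 0, 10, 10), (30, 0, 10, 10)]
        preds = [pred(0, 0, 10, 10, 0.9), pred(30, 0, 10, 10, 0.6),
                 pred(100, 100, 10, 10, 0.3)]
        curve = confidence_curve(gt, preds, 0.5)
        best_idx = np.argmax(curve.f1)
        assert curve.f1[best_idx] == curve.f1.max()
        # dropping only the spurious conf-0.3 box is optimal
        assert 0.3 < curve.best_threshold <= 0.6


class TestMaskAgreement:
    def square(self, x0, y0, side):
        return np.array([[x0, y0], [x0 + side, y0],
                         [x0 + side, y0 + side], [x0, y0 + side]], float)

    def test_identical_masks(self):
        m = mask_from_polygons(0, self.square(0, 0, 10), self.square(3, 4, 2))
        assert mask_agreement(m, m) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_disjoint_complexes(self):
        a = mask_from_polygons(0, self.square(0, 0, 10))
        b = mask_from_polygons(1, self.square(50, 50, 10))
        ciou, aiou = mask_agreement(a, b)
        assert ciou == 0.0 and aiou is None

    def test_half_shifted_square(self):
        a = mask_from_polygons(0, self.square(0, 0, 10))
        b = mask_from_polygons(1, self.square(5, 0, 10))
        ciou, _ = mask_agreement(a, b)
        assert ciou == pytest.approx(1 / 3)

    def test_aperture_term_null_when_absent(self):
        a = mask_from_polygons(0, self.square(0, 0, 10), self.square(3, 4, 2))
        b = mask_from_polygons(1, self.square(0, 0, 10))
        _, aiou = mask_agreement(a, b)
        assert aiou is None
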