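"""COCO-style evaluation: IoU oracle, NMS, AP identities, calibration slope."""

import numpy as np
import pytest

from plexseg import (DEFAULT_IOU_GRID, EvalConfig, InstanceRecord, ValidationError,
                     average_precision, calibration_curve, evaluate, mask_iou, nms)
from conftest import random_blob


def _rect(r0, r1, c0, c1, hw=(32, 32), class_id=0, score=1.0):
    m = np.zeros(hw, dtype=bool)
    m[r0:r1, c0:c1] = True
    return InstanceRecord.from_mask(m, class_id=class_id, score=score)


class TestMaskIoU:
    def test_hand_computed_4_over_12(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0:2, 0:4] = True      # area 8
        b[1:3, 2:6] = True      # area 8, intersection = rows {1} x cols {2,3} = 2
        # inter 2, union 14
        assert mask_iou(a, b) == pytest.approx(2 / 14)

    def test_identical(self, rng):
        m = random_blob(rng)
        assert mask_iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), dtype=bool); a[0, 0] = True
        b = np.zeros((8, 8), dtype=bool); b[7, 7] = True
        assert mask_iou(a, b) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            mask_iou(np.ones((4, 4), dtype=bool), np.ones((5, 5), dtype=bool))

    def test_both_empty(self):
        with pytest.raises(ValidationError):
            mask_iou(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))

    def test_quarter_overlap_oracle(self):
        a = np.zeros((10, 10), dtype=bool); a[0:4, 0:4] = True
        b = np.zeros((10, 10), dtype=bool); b[2:6, 2:6] = True
        assert mask_iou(a, b) == pytest.approx(4 / 28)


class TestNMS:
    def test_duplicate_suppressed(self):
        hi = _rect(2, 10, 2, 10, score=0.9)
        dup = _rect(2, 10, 2, 11, score=0.5)
        far = _rect(20, 28, 20, 28, score=0.7)
        kept = nms([dup, far, hi], 0.5)
        assert [k.score for k in kept] == [0.9, 0.7]

    def test_greedy_oracle(self, rng):
        """Hand-run greedy sweep equals nms() on random blobs."""
        recs = [InstanceRecord.from_mask(random_blob(rng, 24, 24),
                                         score=float(rng.random()))
                for _ in range(20)]
        order = sorted(range(20), key=lambda i: (-recs[i].score, -recs[i].area, i))
        kept_oracle = []
        for i in order:
            if all(mask_iou(recs[i].mask, recs[j].mask) <= 0.5 for j in kept_oracle):
                kept_oracle.append(i)
        got = nms(recs, 0.5)
        assert [id(r) for r in got] == [id(recs[i]) for i in kept_oracle]

    def test_idempotent(self, rng):
        recs = [InstanceRecord.from_mask(random_blob(rng, 24, 24),
                                         score=float(rng.random())) for _ in range(15)]
        once = nms(recs, 0.5)
        twice = nms(once, 0.5)
        assert [id(r) for r in once] == [id(r) for r in twice]

    def test_scoreless_tie_break_by_area(self):
        small = _rect(0, 2, 0, 2)
        big = _rect(10, 20, 10, 20)
        kept = nms([small, big], 0.5)
        assert kept[0].area > kept[1].area


class TestAveragePrecision:
    def test_perfect_single(self):
        gt = [(0, _rect(2, 10, 2, 10))]
        ap, _ = average_precision(gt, gt, 0.5)
        assert ap == 1.0

    def test_empty_preds(self):
        ap, _ = average_precision([], [(0, _rect(2, 10, 2, 10))], 0.5)
        assert ap == 0.0

    def test_empty_gt(self):
        ap, _ = average_precision([(0, _rect(2, 10, 2, 10))], [], 0.5)
        assert ap == 0.0

    def test_strict_inequality_at_threshold(self):
        """IoU exactly 0.5 is not a TP under strict >, but is under >=."""
        gt = [(0, _rect(0, 4, 0, 4))]          # area 16
        pred = [(0, _rect(0, 4, 0, 8))]        # area 32, inter 16, union 32 -> 0.5
        assert mask_iou(gt[0][1].mask, pred[0][1].mask) == 0.5
        ap_strict, _ = average_precision(pred, gt, 0.5, strict=True)
        ap_loose, _ = average_precision(pred, gt, 0.5, strict=False)
        assert ap_strict == 0.0 and ap_loose == 1.0

    def test_step_by_step_oracle(self):
        """Two GT, three preds: TP(0.9), FP(0.8), TP(0.7).

        precision = [1, 1/2, 2/3], recall = [1/2, 1/2, 1]; envelope makes
        precision 1 for r <= 0.5 and 2/3 above -> AP over the 101-point grid.
        """
        gts = [(0, _rect(0, 8, 0, 8)), (0, _rect(16, 24, 16, 24))]
        preds = [(0, _rect(0, 8, 0, 8, score=0.9)),
                 (0, _rect(0, 8, 24, 32, score=0.8)),
                 (0, _rect(16, 24, 16, 24, score=0.7))]
        ap, (prec, rec) = average_precision(preds, gts, 0.5)
        np.testing.assert_allclose(prec, [1, 0.5, 2 / 3])
        np.testing.assert_allclose(rec, [0.5, 0.5, 1.0])
        want = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert ap == pytest.approx(want)

    def test_cross_image_isolation(self):
        """A prediction on image 1 cannot match GT on image 0."""
        gts = [(0, _rect(0, 8, 0, 8))]
        preds = [(1, _rect(0, 8, 0, 8, score=1.0))]
        ap, _ = average_precision(preds, gts, 0.5)
        assert ap == 0.0


class TestEvaluate:
    def _scene(self):
        gt = [_rect(0, 8, 0, 8), _rect(16, 24, 16, 24, class_id=0)]
        return {0: list(gt)}, {0: list(gt)}

    def test_perfect_all_thresholds(self):
        preds, gts = self._scene()
        res = evaluate(preds, gts)
        assert set(res.ap_per_threshold) == set(DEFAULT_IOU_GRID)
        assert len(res.ap_per_threshold) == 9
        assert res.mean_ap == 1.0

    def test_mean_is_mean_over_grid(self):
        preds, gts = self._scene()
        res = evaluate(preds, gts)
        assert res.mean_ap == pytest.approx(
            np.mean(list(res.ap_per_threshold.values())))

    def test_multiclass_average(self):
        gts = {0: [_rect(0, 8, 0, 8, class_id=0), _rect(16, 24, 16, 24, class_id=1)]}
        preds = {0: [_rect(0, 8, 0, 8, class_id=0)]}   # class 1 entirely missed
        res = evaluate(preds, gts)
        assert res.per_class[0][0.5] == 1.0
        assert res.per_class[1][0.5] == 0.0
        assert res.ap_per_threshold[0.5] == 0.5

    def test_unknown_predicted_class_rejected(self):
        gts = {0: [_rect(0, 8, 0, 8, class_id=0)]}
        preds = {0: [_rect(0, 8, 0, 8, class_id=5)]}
        with pytest.raises(ValidationError, match="categories"):
            evaluate(preds, gts, categories=[0, 1])

    def test_empty_gt_rejected(self):
        with pytest.raises(ValidationError):
            evaluate({0: []}, {0: []})

    def test_strata(self):
        gt = _rect(0, 8, 0, 8)
        res = evaluate({0: [gt], 1: []}, {0: [gt], 1: [gt]},
                       strata={0: "easy", 1: "hard"})
        assert res.strata["easy"] == 1.0 and res.strata["hard"] == 0.0

    def test_prediction_order_invariance(self, rng):
        gts = {0: [InstanceRecord.from_mask(random_blob(rng, 24, 24))
                   for _ in range(4)]}
        preds = [InstanceRecord.from_mask(random_blob(rng, 24, 24),
                                          score=float(rng.random()))
                 for _ in range(8)]
        a = evaluate({0: preds}, gts)
        shuffled = [preds[i] for i in rng.permutation(8)]
        b = evaluate({0: shuffled}, gts)
        assert a.mean_ap == b.mean_ap

    def test_invalid_threshold_grid(self):
        with pytest.raises(ValidationError):
            EvalConfig(iou_thresholds=(0.5, 0.5))


class TestCalibration:
    def test_bernoulli_slope_near_one(self, rng):
        """If correctness ~ Bernoulli(score), accuracy at cutoff c approximates
        E[score | score >= c]; for uniform scores this is (1+c)/2, slope 1/2."""
        n = 4000
        gts, preds = [], []
        for i in range(n):
            m = np.zeros((8, 8), dtype=bool)
            m[2:6, 2:6] = True
            s = float(rng.random())
            correct = rng.random() < s
            gts.append((i, InstanceRecord.from_mask(m, class_id=0)))
            preds.append((i, InstanceRecord.from_mask(
                m, class_id=0 if correct else 1, score=s)))
        accs, cuts, slope, pval = calibration_curve(preds, gts)
        assert slope == pytest.approx(0.5, abs=0.06)
        assert pval < 1e-4

    def test_perfectly_calibrated_classifier_flat(self):
        """All matched predictions correct -> accuracy 1 at every cutoff."""
        m = np.zeros((8, 8), dtype=bool)
        m[2:6, 2:6] = True
        gts = [(i, InstanceRecord.from_mask(m)) for i in range(20)]
        preds = [(i, InstanceRecord.from_mask(m, score=0.05 * i)) for i in range(20)]
        accs, cuts, slope, _ = calibration_curve(preds, gts)
        np.testing.assert_allclose(accs, 1.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_no_matches_nan(self):
        a = np.zeros((8, 8), dtype=bool); a[0, 0] = True
        b = np.zeros((8, 8), dtype=bool); b[7, 7] = True
        accs, cuts, slope, _ = calibration_curve(
            [(0, InstanceRecord.from_mask(a))], [(0, InstanceRecord.from_mask(b))])
        assert len(accs) == 0 and np.isnan(slope)
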