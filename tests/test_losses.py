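"""Matching and composite loss: brute-force Hungarian oracle, weighted-sum
identities, permutation invariance, finite-difference gradients."""

import itertools

import numpy as np
import pytest

from plexseg import (LossWeights, MatchResult, ValidationError, composite_loss,
                     denoising_loss, match, pairwise_cost)
from plexseg.autograd import Tensor
from plexseg.detector import DenoiseBlock
from plexseg.losses import giou_np


def _problem(rng, n_pred=5, n_gt=3, k=2, hw=(6, 6), with_masks=True):
    pb = np.column_stack([rng.uniform(0.15, 0.85, (n_pred, 2)),
                          rng.uniform(0.05, 0.35, (n_pred, 2))])
    logits = rng.normal(size=(n_pred, k + 1))
    probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
    pm = rng.normal(size=(n_pred, *hw)) if with_masks else None
    gb = np.column_stack([rng.uniform(0.15, 0.85, (n_gt, 2)),
                          rng.uniform(0.05, 0.35, (n_gt, 2))])
    gl = rng.integers(0, k, n_gt)
    gm = (rng.random((n_gt, *hw)) < 0.4) if with_masks else None
    return pb, logits, probs, pm, gb, gl, gm


class TestGiou:
    def test_identical_boxes(self):
        b = np.array([[0.5, 0.5, 0.2, 0.3]])
        np.testing.assert_allclose(giou_np(b, b), 1.0)

    def test_disjoint_known_value(self):
        # two unit-area-0.01 boxes far apart inside the hull
        a = np.array([0.1, 0.1, 0.1, 0.1])
        b = np.array([0.9, 0.9, 0.1, 0.1])
        # inter=0, union=0.02, hull=0.9x0.9 -> giou = 0 - (0.81-0.02)/0.81
        np.testing.assert_allclose(giou_np(a, b), -(0.81 - 0.02) / 0.81, rtol=1e-12)

    def test_range(self, rng):
        a = np.clip(rng.random((100, 4)), 0.05, 0.95)
        b = np.clip(rng.random((100, 4)), 0.05, 0.95)
        g = giou_np(a, b)
        assert np.all(g <= 1.0 + 1e-12) and np.all(g >= -1.0 - 1e-12)


class TestMatch:
    def test_brute_force_oracle(self, rng):
        """Hungarian result equals exhaustive search over all assignments."""
        w = LossWeights()
        for trial in range(10):
            pb, _, probs, pm, gb, gl, gm = _problem(rng, n_pred=6, n_gt=4)
            cost = pairwise_cost(pb, probs, pm, gb, gl, gm, w)
            res = match(pb, probs, pm, gb, gl, gm, w)
            got = sum(cost[p, g] for p, g in res.pairs)
            best = min(sum(cost[p, g] for g, p in enumerate(perm))
                       for perm in itertools.permutations(range(6), 4))
            assert abs(got - best) < 1e-9
            assert len(res.pairs) == 4

    def test_empty_gt(self, rng):
        pb, _, probs, pm, *_ = _problem(rng)
        res = match(pb, probs, pm, np.zeros((0, 4)), np.zeros(0, dtype=int), None,
                    LossWeights())
        assert res.pairs == []

    def test_identity_on_perfect_predictions(self, rng):
        """Predictions equal to GT (high correct-class prob) match identically."""
        _, _, _, _, gb, gl, gm = _problem(rng, n_gt=4, n_pred=4)
        probs = np.full((4, 3), 0.01)
        probs[np.arange(4), gl] = 0.98
        pm = np.where(gm, 20.0, -20.0)
        res = match(gb, probs, pm, gb, gl, gm, LossWeights())
        assert res.pairs == [(i, i) for i in range(4)]

    def test_gt_permutation_invariance(self, rng):
        pb, _, probs, pm, gb, gl, gm = _problem(rng)
        res = match(pb, probs, pm, gb, gl, gm, LossWeights())
        perm = rng.permutation(len(gb))
        res2 = match(pb, probs, pm, gb[perm], gl[perm], gm[perm], LossWeights())
        mapped = sorted((p, int(perm[g])) for p, g in res2.pairs)
        assert sorted(res.pairs) == mapped


def _tensors(pb, logits, pm):
    return Tensor(pb), Tensor(logits), (Tensor(pm) if pm is not None else None)


class TestCompositeLoss:
    def test_weighted_sum_identity(self, rng):
        """total == lam_cls*L_cls + lam_box*L_box + lam_mask*L_mask exactly."""
        pb, logits, probs, pm, gb, gl, gm = _problem(rng)
        w = LossWeights(lam_cls=3.0, lam_box=0.5, lam_mask=2.0)
        res = match(pb, probs, pm, gb, gl, gm, w)
        total, bd = composite_loss(*_tensors(pb, logits, pm), gb, gl, gm, res, w)
        want = 3.0 * bd["L_cls"] + 0.5 * bd["L_box"] + 2.0 * bd["L_mask"]
        np.testing.assert_allclose(total.item(), want, rtol=1e-12)

    def test_zeroed_lambda_removes_term(self, rng):
        pb, logits, probs, pm, gb, gl, gm = _problem(rng)
        res = match(pb, probs, pm, gb, gl, gm, LossWeights())
        for zeroed, keys in [("lam_box", ("L_cls", "L_mask")),
                             ("lam_mask", ("L_cls", "L_box")),
                             ("lam_cls", ("L_box", "L_mask"))]:
            w = LossWeights(**{zeroed: 0.0})
            total, bd = composite_loss(*_tensors(pb, logits, pm), gb, gl, gm, res, w)
            want = sum(getattr(w, "lam_" + k.split("_")[1].lower()) * bd[k] for k in keys)
            np.testing.assert_allclose(total.item(), want, rtol=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(lam_cls=0.0, lam_box=0.0, lam_mask=0.0)

    def test_perfect_prediction_box_mask_zero(self, rng):
        """Exact boxes and saturated masks -> L1 = 0, GIoU term = 0, Dice ~ 0."""
        _, _, _, _, gb, gl, gm = _problem(rng, n_pred=3, n_gt=3)
        logits = np.full((3, 3), -10.0)
        logits[np.arange(3), gl] = 10.0
        pm = np.where(gm, 40.0, -40.0)
        res = MatchResult(pairs=[(i, i) for i in range(3)])
        total, bd = composite_loss(*_tensors(gb, logits, pm), gb, gl, gm, res,
                                   LossWeights())
        assert bd["l1"] < 1e-12 and bd["giou"] < 1e-9
        assert bd["bce"] < 1e-12 and bd["dice"] < 1e-3
        assert bd["L_cls"] < 1e-6

    def test_no_masks_mode(self, rng):
        pb, logits, probs, _, gb, gl, _ = _problem(rng, with_masks=False)
        res = match(pb, probs, None, gb, gl, None, LossWeights())
        total, bd = composite_loss(Tensor(pb), Tensor(logits), None, gb, gl, None,
                                   res, LossWeights())
        assert bd["L_mask"] == 0.0 and np.isfinite(total.item())

    def test_empty_gt_classification_only(self, rng):
        pb, logits, *_ = _problem(rng)
        total, bd = composite_loss(Tensor(pb), Tensor(logits), None,
                                   np.zeros((0, 4)), np.zeros(0, dtype=int), None,
                                   MatchResult(pairs=[]), LossWeights())
        assert bd["L_box"] == 0.0 and bd["L_mask"] == 0.0 and bd["L_cls"] > 0

    def test_finite_difference_gradient(self, rng):
        """Central finite differences on every input tensor (rel err < 1e-4)."""
        pb, logits, probs, pm, gb, gl, gm = _problem(rng, n_pred=4, n_gt=2, hw=(4, 4))
        w = LossWeights()
        res = match(pb, probs, pm, gb, gl, gm, w)

        def f(pb_, lg_, pm_):
            t, _ = composite_loss(Tensor(pb_), Tensor(lg_), Tensor(pm_),
                                  gb, gl, gm, res, w)
            return t

        tb = Tensor(pb, requires_grad=True)
        tl = Tensor(logits, requires_grad=True)
        tm = Tensor(pm, requires_grad=True)
        total, _ = composite_loss(tb, tl, tm, gb, gl, gm, res, w)
        total.backward()
        eps = 1e-6
        for arr, tensor in ((pb, tb), (logits, tl), (pm, tm)):
            flat = arr.ravel()
            idx = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                bump = np.zeros_like(flat)
                bump[i] = eps
                hi = f(*(a + bump.reshape(a.shape) if a is arr else a
                         for a in (pb, logits, pm))).item()
                lo = f(*(a - bump.reshape(a.shape) if a is arr else a
                         for a in (pb, logits, pm))).item()
                fd = (hi - lo) / (2 * eps)
                an = tensor.grad.ravel()[i]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), (fd, an)


class TestDenoisingLoss:
    def _block(self, rng, n_gt=2, groups=2):
        n = n_gt * 2 * groups
        positive = np.tile(np.repeat([True, False], n_gt), groups)
        gt_index = np.tile(np.arange(n_gt), 2 * groups)
        group = np.repeat(np.arange(groups), 2 * n_gt)
        return DenoiseBlock(boxes_logit=rng.normal(size=(n, 4)),
                            labels=np.zeros(n, dtype=int), positive=positive,
                            gt_index=gt_index, group=group,
                            deltas=np.zeros((n, 4)))

    def test_negatives_only_class_supervised(self, rng):
        """Zeroing lam_cls removes all loss contribution from negatives."""
        _, _, _, _, gb, gl, gm = _problem(rng, n_gt=2)
        block = self._block(rng)
        n = block.n
        boxes = Tensor(np.clip(rng.random((n, 4)), 0.1, 0.9), requires_grad=True)
        logits = Tensor(rng.normal(size=(n, 3)), requires_grad=True)
        masks = Tensor(rng.normal(size=(n, 6, 6)), requires_grad=True)
        total, _ = denoising_loss(boxes, logits, masks, gb, gl, gm, block,
                                  LossWeights(lam_cls=0.0))
        total.backward()
        neg = ~block.positive
        assert np.allclose(boxes.grad[neg], 0.0)
        assert np.allclose(masks.grad[neg], 0.0)
        assert np.any(boxes.grad[block.positive] != 0)

    def test_perfect_positives_zero_box_loss(self, rng):
        _, _, _, _, gb, gl, gm = _problem(rng, n_gt=2)
        block = self._block(rng)
        boxes = np.asarray(gb)[block.gt_index]
        logits = np.full((block.n, 3), -10.0)
        logits[block.positive, gl[block.gt_index[block.positive]]] = 10.0
        logits[~block.positive, 2] = 10.0
        masks = np.where(gm[block.gt_index], 40.0, -40.0)
        total, bd = denoising_loss(Tensor(boxes), Tensor(logits), Tensor(masks),
                                   gb, gl, gm, block, LossWeights())
        assert bd["L_box"] < 1e-9 and bd["L_cls"] < 1e-6

    def test_empty_block_zero(self, rng):
        total, bd = denoising_loss(Tensor(np.zeros((0, 4))), Tensor(np.zeros((0, 3))),
                                   None, np.zeros((0, 4)), np.zeros(0, dtype=int),
                                   None, DenoiseBlock.empty(), LossWeights())
        assert total.item() == 0.0 and bd == {}
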