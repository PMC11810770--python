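"""Detector: token bookkeeping, query selection, denoising noise bounds,
decoder refinement contracts, classification head."""

import numpy as np
import pytest

from plexseg import (BBox, DetectorConfig, InstanceRecord, NoiseConfig, ValidationError,
                     classify, make_denoising_queries)
from plexseg.autograd import Tensor
from plexseg.backbone import FeaturePyramid
from plexseg.detector import DINODetector, denoise_attention_mask, inverse_sigmoid


@pytest.fixture(scope="module")
def detector():
    cfg = DetectorConfig(d_model=16, n_heads=2, n_encoder_layers=1, n_decoder_layers=2,
                         n_queries=20, n_classes=2)
    return DINODetector(cfg, [(8, 12), (16, 24)], np.random.default_rng(0))


def _pyramid(rng, shapes=((8, 12, 8, 8), (16, 24, 4, 4))):
    return FeaturePyramid(levels=[(s, Tensor(rng.normal(size=(d, h, w))))
                                  for s, d, h, w in shapes])


class TestEncode:
    def test_token_count(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        assert mem.n_tokens == 8 * 8 + 4 * 4

    def test_positional_embeddings_distinct(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        assert not np.allclose(mem.pos[0], mem.pos[1])

    def test_level_index_bijection(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        cells = {tuple(row) for row in mem.level_index}
        expected = {(s, r, c) for s, h, w in mem.level_shapes
                    for r in range(h) for c in range(w)}
        assert cells == expected and len(mem.level_index) == len(expected)

    def test_token_budget(self, rng):
        cfg = DetectorConfig(d_model=16, n_heads=2, n_queries=5, n_classes=1, max_tokens=10)
        det = DINODetector(cfg, [(8, 12)], np.random.default_rng(0))
        with pytest.raises(ValidationError, match="budget"):
            det.encode(_pyramid(rng, shapes=((8, 12, 8, 8),)))


class TestSelectQueries:
    def test_all_tokens_when_n_equals_count(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        qs = detector.select_queries(mem, n=mem.n_tokens)
        assert sorted(qs.top_idx.tolist()) == list(range(mem.n_tokens))

    def test_anchors_in_unit_box(self, detector, rng):
        qs = detector.select_queries(detector.encode(_pyramid(rng)), n=10)
        q = qs.q_pos
        assert np.all((q >= 0) & (q <= 1)) and np.all(q[:, 2:] > 0)

    def test_top_ranked_matches_argmax(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        qs = detector.select_queries(mem, n=5)
        # brute-force oracle over the shared class head's object logits
        logits = qs.enc_logits.data[:, :-1].max(axis=1)
        assert qs.top_idx[0] == int(np.argmax(logits))
        assert list(qs.top_idx) == list(np.argsort(-logits, kind="stable")[:5])

    def test_invalid_n(self, detector, rng):
        with pytest.raises(ValidationError):
            detector.select_queries(detector.encode(_pyramid(rng)), n=0)


def _gt(boxes_norm, hw=(64, 64)):
    H, W = hw
    out = []
    for cx, cy, w, h in boxes_norm:
        mask = np.zeros(hw, dtype=bool)
        x0 = int((cx - w / 2) * W)
        y0 = int((cy - h / 2) * H)
        mask[y0:y0 + max(int(h * H), 1), x0:x0 + max(int(w * W), 1)] = True
        out.append(InstanceRecord(mask=mask,
                                  box=BBox(cx, cy, w, h, frame="normalized").to_pixel(H, W),
                                  class_id=0))
    return out


class TestDenoising:
    def test_positive_bounds_lambda1(self):
        """Positive noise obeys the four small-noise inequalities for lam1=0.4."""
        gt = _gt([(0.5, 0.5, 0.2, 0.2)])
        noise = NoiseConfig(lam1=0.4, lam2=1.0, n_groups=1, label_flip_prob=0.0)
        rng = np.random.default_rng(0)
        for _ in range(500):
            block = make_denoising_queries(gt, noise, K=1, rng=rng, image_hw=(64, 64))
            dx, dy, dw, dh = np.abs(block.deltas[block.positive][0])
            assert dx < 0.4 * 0.2 / 2 and dy < 0.4 * 0.2 / 2
            assert dw < 0.4 * 0.2 and dh < 0.4 * 0.2

    def test_zero_noise_limit(self):
        gt = _gt([(0.5, 0.5, 0.25, 0.25), (0.25, 0.25, 0.125, 0.125)])
        noise = NoiseConfig(lam1=1e-12, lam2=1.0, n_groups=2, label_flip_prob=0.0)
        block = make_denoising_queries(gt, noise, K=1, rng=np.random.default_rng(1),
                                       image_hw=(64, 64))
        pos = block.boxes_logit[block.positive]
        expected = np.stack([inverse_sigmoid(g.box.to_normalized(64, 64).as_array())
                             for g in gt] * 2)
        np.testing.assert_allclose(pos, expected, atol=1e-6)

    def test_negative_annulus(self):
        """Negatives violate every lam1 bound while satisfying every lam2 bound."""
        gt = _gt([(0.5, 0.5, 0.3, 0.4)])
        noise = NoiseConfig(lam1=0.4, lam2=1.0, n_groups=5, label_flip_prob=0.0)
        rng = np.random.default_rng(2)
        w, h = 0.3, 0.4
        scale = np.array([w / 2, h / 2, w, h])
        n_draws = 0
        while n_draws < 10000:
            block = make_denoising_queries(gt, noise, K=1, rng=rng, image_hw=(64, 64))
            neg = np.abs(block.deltas[~block.positive])
            assert np.all(neg >= 0.4 * scale)      # violates the lam1 bound
            assert np.all(neg < 1.0 * scale)       # satisfies the lam2 bound
            n_draws += len(neg)

    def test_empty_gt_empty_block(self):
        block = make_denoising_queries([], NoiseConfig(), K=1,
                                       rng=np.random.default_rng(0), image_hw=(64, 64))
        assert block.n == 0
        assert denoise_attention_mask(5, block) is None

    def test_group_isolation_mask(self):
        gt = _gt([(0.5, 0.5, 0.2, 0.2)] * 2)
        block = make_denoising_queries(gt, NoiseConfig(n_groups=2), K=1,
                                       rng=np.random.default_rng(0), image_hw=(64, 64))
        mask = denoise_attention_mask(3, block)
        n = 3 + block.n
        assert mask.shape == (n, n)
        assert np.all(mask[:3, :3] == 0)            # matching sees matching
        assert np.all(mask[:3, 3:] < 0)             # matching never sees denoise
        assert np.all(mask[3:, :3] < 0)             # denoise never sees matching
        g = block.group
        cross = g[:, None] != g[None, :]
        assert np.all(mask[3:, 3:][cross] < 0)
        assert np.all(mask[3:, 3:][~cross] == 0)

    def test_invalid_noise_config(self):
        with pytest.raises(ValidationError):
            NoiseConfig(lam1=1.0, lam2=0.4)


class TestDecode:
    def test_refinement_identity_at_init(self, detector, rng):
        """With the zero-initialized final box layer, output = input anchors."""
        fresh = DINODetector(detector.cfg, [(8, 12), (16, 24)], np.random.default_rng(7))
        mem = fresh.encode(_pyramid(rng))
        qs = fresh.select_queries(mem, n=8)
        out = fresh.decode(mem, qs)
        np.testing.assert_allclose(out.boxes_per_layer[0].data, qs.q_pos, atol=1e-9)

    def test_boxes_stay_in_unit_box(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        qs = detector.select_queries(mem, n=10)
        gt = _gt([(0.5, 0.5, 0.2, 0.2)] * 3)
        block = make_denoising_queries(gt, NoiseConfig(), K=2,
                                       rng=np.random.default_rng(1), image_hw=(64, 64))
        out = detector.decode(mem, qs, block)
        for boxes in out.boxes_per_layer:
            assert np.all((boxes.data >= 0) & (boxes.data <= 1))

    def test_query_count_contract(self, detector, rng):
        mem = detector.encode(_pyramid(rng))
        qs = detector.select_queries(mem, n=10)
        gt = _gt([(0.5, 0.5, 0.2, 0.2)] * 4)
        block = make_denoising_queries(gt, NoiseConfig(n_groups=3), K=2,
                                       rng=np.random.default_rng(1), image_hw=(64, 64))
        out = detector.decode(mem, qs, block)
        assert out.n_match == 10
        boxes, logits, q_c = out.matching()
        assert boxes.shape == (10, 4) and logits.shape == (10, 3) and q_c.shape[0] == 10

    def test_denoise_does_not_leak_into_matching(self, detector, rng):
        """Autograd probe: matching-query outputs are independent of the
        denoising block content (gradient of matching logits w.r.t. the label
        embedding, which only denoise queries consume, is zero)."""
        mem = detector.encode(_pyramid(rng))
        qs = detector.select_queries(mem, n=6)
        gt = _gt([(0.5, 0.5, 0.2, 0.2)] * 2)
        block = make_denoising_queries(gt, NoiseConfig(n_groups=1), K=2,
                                       rng=np.random.default_rng(3), image_hw=(64, 64))
        detector.zero_grad()
        out = detector.decode(mem, qs, block)
        out.logits_per_layer[-1][:6].sum().backward()
        grad = detector.label_embed.grad
        assert grad is None or np.allclose(grad, 0.0)


class TestClassify:
    def test_equal_logits_two_way(self):
        probs, pred, score = classify(np.array([0.0, 0.0]))
        np.testing.assert_allclose(probs, [0.5, 0.5])
        assert pred == 0 and score == 0.5

    def test_shift_invariance(self, rng):
        z = rng.normal(size=(50, 4))
        a = classify(z)
        b = classify(z + 123.456)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_array_equal(a[1], b[1])

    def test_direct_formula(self):
        z = np.array([1.0, 2.0, 3.0, 0.0])
        probs, pred, score = classify(z)
        denom = np.exp(1) + np.exp(2) + np.exp(3) + 1
        np.testing.assert_allclose(probs, np.exp(z) / denom, rtol=1e-12)
        assert pred == 2
        np.testing.assert_allclose(score, np.exp(3) / denom, rtol=1e-12)

    def test_simplex_property(self, rng):
        z = rng.normal(scale=5, size=(1000, 5))
        probs, pred, score = classify(z)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(score, probs[:, :-1].max(-1))
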