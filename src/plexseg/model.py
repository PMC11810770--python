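"""End-to-end model: backbone + detector + mask head wired together.

The forward pass follows the method's order: multiscale feature extraction,
encoder over flattened tokens, pixel embedding map, mixed query selection
with unified (mask-informed) anchor initialization, contrastive denoising
(training only), iterative decoder refinement, and per-query classification
plus mask prediction by dot product with the pixel map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np

from .autograd import Tensor, no_grad
from .backbone import BackboneConfig, SwinBackbone, default_tiny_config
from .data import BBox, InstanceRecord, MultiplexImage
from .detector import (DINODetector, DetectorConfig, NoiseConfig, classify,
                       make_denoising_queries)
from .losses import LossWeights, composite_loss, denoising_loss, match
from .mask_head import (MaskHead, MaskHeadConfig, binarize_masks, predict_masks,
                        unified_query_init_from_masks, upsample_mask_logits)
from .nn import Module

__all__ = ["ModelConfig", "SegmentationModel", "infer",
           "save_checkpoint", "load_checkpoint", "tiny_model_config"]


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    mask_head: MaskHeadConfig = field(default_factory=MaskHeadConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    detector_strides: tuple[int, ...] = (8,)   # pyramid levels fed to the encoder
    aux_encoder_loss: bool = True
    init_seed: int = 0


def tiny_model_config(in_channels: int = 2, n_classes: int = 1,
                      n_queries: int = 100, seed: int = 0) -> ModelConfig:
    """Desk-scale configuration: embed_dim 32, 2 decoder layers, dense attention."""
    return ModelConfig(
        backbone=default_tiny_config(in_channels),
        detector=DetectorConfig(d_model=32, n_heads=4, n_encoder_layers=1,
                                n_decoder_layers=2, n_queries=n_queries,
                                n_classes=n_classes, attention="dense"),
        mask_head=MaskHeadConfig(stride=4, hidden_dim=32),
        detector_strides=(8,),
        init_seed=seed)


def _downsample_mask(mask: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Average-pool a binary mask to the mask-head grid (soft target in [0,1])."""
    H, W = mask.shape
    ho, wo = out_hw
    fh, fw = H // ho, W // wo
    if fh * ho == H and fw * wo == W and fh == fw and fh >= 1:
        return mask.reshape(ho, fh, wo, fw).mean(axis=(1, 3))
    # non-integer factor: area sampling via cumulative sums
    ys = np.linspace(0, H, ho + 1).astype(int)
    xs = np.linspace(0, W, wo + 1).astype(int)
    cs = np.pad(mask.astype(np.float64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    out = (cs[ys[1:], :][:, xs[1:]] - cs[ys[:-1], :][:, xs[1:]]
           - cs[ys[1:], :][:, xs[:-1]] + cs[ys[:-1], :][:, xs[:-1]])
    areas = np.outer(np.diff(ys), np.diff(xs))
    return out / np.maximum(areas, 1)


class SegmentationModel(Module):
    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.init_seed)
        self.cfg = cfg
        self.backbone = SwinBackbone(cfg.backbone, rng)
        level_dims = [(s, cfg.backbone.stage_dim(int(np.log2(s / 4))))
                      for s in cfg.detector_strides]
        self.detector = DINODetector(cfg.detector, level_dims, rng)
        self.mask_head = MaskHead(cfg.mask_head,
                                  cfg.backbone.stage_dim(int(np.log2(cfg.mask_head.stride / 4))),
                                  rng)

    # ------------------------------------------------------------------ core
    def forward_raw(self, image: MultiplexImage, gt: list[InstanceRecord] | None = None,
                    noise_rng: np.random.Generator | None = None,
                    n_queries: int | None = None):
        """Shared forward pass.  With `gt`, a denoising block is attached."""
        cfg = self.cfg
        pyramid = self.backbone(image)
        memory = self.detector.encode(pyramid)
        emap = self.mask_head.build_pixel_map(pyramid, memory)
        queries = self.detector.select_queries(memory, n_queries)
        # unified query initialization: anchors from encoder-stage mask proposals
        init_logits = predict_masks(memory.C_e[queries.top_idx], emap)
        queries.q_pos_logit = unified_query_init_from_masks(
            init_logits.data, queries.q_pos_logit, cfg.mask_head.threshold)
        denoise = None
        if gt:
            rng = noise_rng if noise_rng is not None else np.random.default_rng(0)
            denoise = make_denoising_queries(
                gt, cfg.noise, cfg.detector.n_classes, rng,
                (image.height, image.width), max_total=queries.n)
        decoded = self.detector.decode(memory, queries, denoise)
        mask_logits = predict_masks(decoded.q_c, emap)      # (N_total, H', W')
        return pyramid, memory, emap, queries, denoise, decoded, mask_logits

    def training_loss(self, image: MultiplexImage, gt: list[InstanceRecord],
                      noise_rng: np.random.Generator) -> tuple[Tensor, dict]:
        """Composite loss with per-decoder-layer auxiliaries and denoising."""
        cfg = self.cfg
        H, W = image.height, image.width
        out = self.forward_raw(image, gt=gt, noise_rng=noise_rng)
        _, memory, emap, queries, denoise, decoded, mask_logits = out
        n = decoded.n_match
        hw_small = emap.E.shape[1:]
        gt_boxes = np.stack([g.box.to_normalized(H, W).as_array() for g in gt]) \
            if gt else np.zeros((0, 4))
        gt_labels = np.array([g.class_id for g in gt], dtype=int)
        gt_small = np.stack([_downsample_mask(g.mask, hw_small) for g in gt]) \
            if gt else None
        weights = cfg.loss
        total = Tensor(0.0)
        breakdown = {}
        n_layers = len(decoded.boxes_per_layer)
        for li in range(n_layers):
            boxes_l = decoded.boxes_per_layer[li][:n]
            logits_l = decoded.logits_per_layer[li][:n]
            final = li == n_layers - 1
            ml = mask_logits[:n] if final else None
            probs = classify(logits_l.data)[0]
            m = match(boxes_l.data, probs, ml.data if ml is not None else None,
                      gt_boxes, gt_labels, gt_small if final else None, weights)
            loss_l, bd = composite_loss(boxes_l, logits_l, ml, gt_boxes, gt_labels,
                                        gt_small if final else None, m, weights)
            total = total + loss_l
            if final:
                breakdown.update(bd)
        if denoise is not None and denoise.n:
            dn_boxes = decoded.boxes_per_layer[-1][n:]
            dn_logits = decoded.logits_per_layer[-1][n:]
            dn_masks = mask_logits[n:]
            dn_loss, dn_bd = denoising_loss(dn_boxes, dn_logits, dn_masks,
                                            gt_boxes, gt_labels, gt_small,
                                            denoise, weights)
            total = total + dn_loss
            breakdown["L_dn"] = dn_loss.item()
        if cfg.aux_encoder_loss and len(gt):
            top = queries.top_idx
            enc_boxes = queries.enc_proposals[top]
            enc_logits = queries.enc_logits[top]
            probs = classify(enc_logits.data)[0]
            m = match(enc_boxes.data, probs, None, gt_boxes, gt_labels, None, weights)
            enc_loss, _ = composite_loss(enc_boxes, enc_logits, None, gt_boxes,
                                         gt_labels, None, m, weights)
            total = total + enc_loss
        breakdown["total"] = total.item()
        return total, breakdown


def infer(model: SegmentationModel, image: MultiplexImage,
          n_queries: int | None = None, score_threshold: float = 0.3) -> list[InstanceRecord]:
    """Predict scored instances: every query yields a candidate; candidates
    with confidence >= `score_threshold` are returned sorted by descending
    score.  A candidate whose binarized mask is empty falls back to its
    predicted box rectangle so the query count contract holds at threshold 0.
    """
    H, W = image.height, image.width
    with no_grad():
        out = model.forward_raw(image, n_queries=n_queries)
    _, _, _, _, _, decoded, mask_logits = out
    n = decoded.n_match
    boxes = decoded.boxes_per_layer[-1].data[:n]
    _, pred_cls, scores = classify(decoded.logits_per_layer[-1].data[:n])
    full_logits = upsample_mask_logits(mask_logits.data[:n], (H, W))
    binary = binarize_masks(full_logits, model.cfg.mask_head.threshold)
    keep = np.flatnonzero(scores >= score_threshold)
    order = keep[np.lexsort((keep, -binary[keep].sum(axis=(1, 2)), -scores[keep]))]
    records = []
    for i in order:
        mask = binary[i]
        if not mask.any():
            cx, cy, bw, bh = boxes[i] * [W, H, W, H]
            r0, r1 = int(max(cy - bh / 2, 0)), int(min(max(cy + bh / 2, 1), H))
            c0, c1 = int(max(cx - bw / 2, 0)), int(min(max(cx + bw / 2, 1), W))
            mask = np.zeros((H, W), dtype=bool)
            mask[r0:max(r1, r0 + 1), c0:max(c1, c0 + 1)] = True
        box = BBox(*(boxes[i] * [W, H, W, H]), frame="pixel")
        records.append(InstanceRecord(mask=mask, box=box, class_id=int(pred_cls[i]),
                                      score=float(scores[i])))
    return records


# ------------------------------------------------------------- serialization

def _config_to_dict(cfg: ModelConfig) -> dict:
    return asdict(cfg)


def _config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(
        backbone=BackboneConfig(**{**d["backbone"],
                                   "depths": tuple(d["backbone"]["depths"]),
                                   "num_heads": tuple(d["backbone"]["num_heads"]),
                                   "out_strides": tuple(d["backbone"]["out_strides"])}),
        detector=DetectorConfig(**d["detector"]),
        mask_head=MaskHeadConfig(**d["mask_head"]),
        noise=NoiseConfig(**d["noise"]),
        loss=LossWeights(**d["loss"]),
        detector_strides=tuple(d["detector_strides"]),
        aux_encoder_loss=d["aux_encoder_loss"],
        init_seed=d["init_seed"])


def save_checkpoint(path, model: SegmentationModel):
    path = Path(path)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    path.with_suffix(".json").write_text(json.dumps(_config_to_dict(model.cfg)))


def load_checkpoint(path) -> SegmentationModel:
    path = Path(path)
    cfg = _config_from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = SegmentationModel(cfg)
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model
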