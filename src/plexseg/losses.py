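"""Bipartite matching and the composite training loss.

Set prediction: predictions are matched one-to-one to ground truth by the
Hungarian algorithm on a pair cost built from the same term definitions as
the training loss (class probability, L1 + GIoU box terms, BCE + Dice mask
terms), so matching optimizes the trained objective.  The total loss is

    Loss = lam_cls * L_cls + lam_box * L_box + lam_mask * L_mask

with L_box = w_l1 * L1 + w_giou * (1 - GIoU) over matched pairs,
L_mask = w_bce * BCE + w_dice * Dice over matched pairs, and L_cls a softmax
focal loss over K+1 classes on every query (unmatched queries target the
"no object" slot).  The denoising branch supervises its queries on known
correspondences without matching: positives regress to their own ground
truth, negatives are pushed to "no object".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autograd import Tensor
from .data import ValidationError
from .detector import DenoiseBlock

__all__ = ["LossWeights", "MatchResult", "match", "composite_loss", "denoising_loss",
           "pairwise_cost"]


@dataclass
class LossWeights:
    lam_cls: float = 4.0
    lam_box: float = 1.0
    lam_mask: float = 1.0
    w_l1: float = 5.0
    w_giou: float = 2.0
    w_bce: float = 5.0
    w_dice: float = 5.0
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25   # weight of the "no object" slot; object classes get 1-alpha... see methods

    def __post_init__(self):
        vals = (self.lam_cls, self.lam_box, self.lam_mask)
        if any(v < 0 for v in vals):
            raise ValidationError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValidationError("at least one of lam_cls/lam_box/lam_mask must be positive")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]    # (prediction index, ground-truth index)

    @property
    def pred_idx(self) -> np.ndarray:
        return np.array([p for p, _ in self.pairs], dtype=int)

    @property
    def gt_idx(self) -> np.ndarray:
        return np.array([g for _, g in self.pairs], dtype=int)


# -------------------------------------------------------------- numpy terms

def _boxes_xyxy(b: np.ndarray) -> tuple:
    return (b[..., 0] - b[..., 2] / 2, b[..., 1] - b[..., 3] / 2,
            b[..., 0] + b[..., 2] / 2, b[..., 1] + b[..., 3] / 2)


def giou_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Generalized IoU of cxcywh boxes; broadcasts over leading axes."""
    ax0, ay0, ax1, ay1 = _boxes_xyxy(a)
    bx0, by0, bx1, by1 = _boxes_xyxy(b)
    iw = np.clip(np.minimum(ax1, bx1) - np.maximum(ax0, bx0), 0, None)
    ih = np.clip(np.minimum(ay1, by1) - np.maximum(ay0, by0), 0, None)
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    cw = np.maximum(ax1, bx1) - np.minimum(ax0, bx0)
    ch = np.maximum(ay1, by1) - np.minimum(ay0, by0)
    carea = cw * ch
    return inter / union - (carea - union) / carea


def pairwise_cost(pred_boxes: np.ndarray, pred_probs: np.ndarray,
                  pred_mask_logits: np.ndarray | None,
                  gt_boxes: np.ndarray, gt_labels: np.ndarray,
                  gt_masks: np.ndarray | None, weights: LossWeights) -> np.ndarray:
    """(N_pred, N_gt) matching cost with the loss's term definitions."""
    N, M = len(pred_boxes), len(gt_boxes)
    cost = np.zeros((N, M))
    cost += weights.lam_cls * (-pred_probs[:, gt_labels])
    l1 = np.abs(pred_boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    gi = giou_np(pred_boxes[:, None, :], gt_boxes[None, :, :])
    cost += weights.lam_box * (weights.w_l1 * l1 + weights.w_giou * (1.0 - gi))
    if pred_mask_logits is not None and gt_masks is not None and M:
        x = pred_mask_logits.reshape(N, -1)
        z = gt_masks.reshape(M, -1).astype(np.float64)
        npix = x.shape[1]
        # stable BCE-with-logits, averaged per pixel: pairwise via separable terms
        softplus = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        bce = (softplus.sum(1)[:, None] - x @ z.T) / npix
        p = 1.0 / (1.0 + np.exp(-x))
        inter = p @ z.T
        dice = 1.0 - (2 * inter + 1.0) / (p.sum(1)[:, None] + z.sum(1)[None, :] + 1.0)
        cost += weights.lam_mask * (weights.w_bce * bce + weights.w_dice * dice)
    if not np.all(np.isfinite(cost)):
        raise FloatingPointError("non-finite matching cost")
    return cost


def match(pred_boxes: np.ndarray, pred_probs: np.ndarray,
          pred_mask_logits: np.ndarray | None,
          gt_boxes: np.ndarray, gt_labels: np.ndarray,
          gt_masks: np.ndarray | None, weights: LossWeights) -> MatchResult:
    """Minimum-cost bipartite assignment (Hungarian); empty GT -> no pairs."""
    if len(gt_boxes) == 0:
        return MatchResult(pairs=[])
    cost = pairwise_cost(pred_boxes, pred_probs, pred_mask_logits,
                         gt_boxes, gt_labels, gt_masks, weights)
    rows, cols = linear_sum_assignment(cost)
    return MatchResult(pairs=sorted(zip(rows.tolist(), cols.tolist()), key=lambda rc: rc[1]))


# ------------------------------------------------------------- tensor terms

def _bce_with_logits(x: Tensor, z: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy from logits."""
    zt = Tensor(np.asarray(z, dtype=np.float64))
    return x.relu() - x * zt + ((-x.abs()).exp() + 1.0).log()


def _giou_t(a: Tensor, b: np.ndarray) -> Tensor:
    bt = Tensor(np.asarray(b, dtype=np.float64))
    ax0 = a[:, 0] - a[:, 2] * 0.5
    ay0 = a[:, 1] - a[:, 3] * 0.5
    ax1 = a[:, 0] + a[:, 2] * 0.5
    ay1 = a[:, 1] + a[:, 3] * 0.5
    bx0, by0 = bt[:, 0] - bt[:, 2] * 0.5, bt[:, 1] - bt[:, 3] * 0.5
    bx1, by1 = bt[:, 0] + bt[:, 2] * 0.5, bt[:, 1] + bt[:, 3] * 0.5
    iw = ax1.minimum(bx1) - ax0.maximum(bx0)
    ih = ay1.minimum(by1) - ay0.maximum(by0)
    inter = iw.maximum(0.0) * ih.maximum(0.0)
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    cw = ax1.maximum(bx1) - ax0.minimum(bx0)
    ch = ay1.maximum(by1) - ay0.minimum(by0)
    carea = cw * ch + 1e-12
    return inter / (union + 1e-12) - (carea - union) / carea


def focal_class_loss(logits: Tensor, targets: np.ndarray, weights: LossWeights,
                     n_norm: float) -> Tensor:
    """Softmax focal loss over K+1 classes.

    alpha weights the dominant "no object" targets down (alpha) and object
    targets up (1 - alpha), following the focal-loss convention that the rare
    class carries the larger weight; gamma focuses on hard examples.
    Normalized by the ground-truth instance count.
    """
    n, kp1 = logits.shape
    logp = logits.log_softmax(axis=-1)
    idx = (np.arange(n), np.asarray(targets, dtype=int))
    logp_t = logp[idx]
    p_t = logp_t.exp()
    alpha_t = np.where(np.asarray(targets) == kp1 - 1, weights.focal_alpha,
                       1.0 - weights.focal_alpha)
    loss = Tensor(alpha_t) * (1.0 - p_t) ** weights.focal_gamma * (-logp_t)
    return loss.sum() * (1.0 / max(n_norm, 1.0))


def _box_terms(pred: Tensor, gt: np.ndarray) -> tuple[Tensor, Tensor]:
    l1 = (pred - Tensor(gt)).abs().sum() * (1.0 / max(len(gt), 1))
    gi = (1.0 - _giou_t(pred, gt)).sum() * (1.0 / max(len(gt), 1))
    return l1, gi


def _mask_terms(pred_logits: Tensor, gt: np.ndarray) -> tuple[Tensor, Tensor]:
    m = len(gt)
    flatp = pred_logits.reshape(m, -1)
    z = gt.reshape(m, -1).astype(np.float64)
    bce = _bce_with_logits(flatp, z).mean(axis=1).sum() * (1.0 / max(m, 1))
    p = flatp.sigmoid()
    zt = Tensor(z)
    inter = (p * zt).sum(axis=1)
    dice = (1.0 - (2.0 * inter + 1.0) / (p.sum(axis=1) + zt.sum(axis=1) + 1.0))
    return bce, dice.sum() * (1.0 / max(m, 1))


def composite_loss(pred_boxes: Tensor, pred_logits: Tensor,
                   pred_mask_logits: Tensor | None,
                   gt_boxes: np.ndarray, gt_labels: np.ndarray,
                   gt_masks: np.ndarray | None,
                   matches: MatchResult, weights: LossWeights,
                   n_norm: float | None = None) -> tuple[Tensor, dict]:
    """Weighted sum lam_cls*L_cls + lam_box*L_box + lam_mask*L_mask.

    Classification covers every query (matched -> its GT class, unmatched ->
    "no object"); box and mask terms cover matched pairs only.  Returns the
    scalar loss and a breakdown of the unweighted terms.
    """
    n, kp1 = pred_logits.shape
    no_object = kp1 - 1
    targets = np.full(n, no_object)
    if matches.pairs:
        targets[matches.pred_idx] = np.asarray(gt_labels)[matches.gt_idx]
    norm = float(n_norm if n_norm is not None else max(len(gt_boxes), 1))
    l_cls = focal_class_loss(pred_logits, targets, weights, norm)
    zero = Tensor(0.0)
    l1 = gi = bce = dice = zero
    if matches.pairs:
        pi, gi_idx = matches.pred_idx, matches.gt_idx
        l1, gi = _box_terms(pred_boxes[pi], np.asarray(gt_boxes)[gi_idx])
        if pred_mask_logits is not None and gt_masks is not None:
            bce, dice = _mask_terms(pred_mask_logits[pi], np.asarray(gt_masks)[gi_idx])
    l_box = weights.w_l1 * l1 + weights.w_giou * gi
    l_mask = weights.w_bce * bce + weights.w_dice * dice
    total = weights.lam_cls * l_cls + weights.lam_box * l_box + weights.lam_mask * l_mask
    breakdown = {"L_cls": l_cls.item(), "L_box": l_box.item(), "L_mask": l_mask.item(),
                 "l1": l1.item(), "giou": gi.item(), "bce": bce.item(), "dice": dice.item()}
    return total, breakdown


def denoising_loss(dn_boxes: Tensor, dn_logits: Tensor, dn_mask_logits: Tensor | None,
                   gt_boxes: np.ndarray, gt_labels: np.ndarray,
                   gt_masks: np.ndarray | None, block: DenoiseBlock,
                   weights: LossWeights) -> tuple[Tensor, dict]:
    """Loss on the denoising branch's known correspondences.

    Positive queries regress to their own ground-truth box/mask/class;
    negatives are supervised to "no object" only.
    """
    if block.n == 0:
        return Tensor(0.0), {}
    kp1 = dn_logits.shape[-1]
    no_object = kp1 - 1
    targets = np.where(block.positive,
                       np.asarray(gt_labels)[block.gt_index], no_object)
    norm = max(int(block.positive.sum()), 1)
    l_cls = focal_class_loss(dn_logits, targets, weights, norm)
    pos = np.flatnonzero(block.positive)
    l1 = gi = bce = dice = Tensor(0.0)
    if len(pos):
        gt_of = block.gt_index[pos]
        l1, gi = _box_terms(dn_boxes[pos], np.asarray(gt_boxes)[gt_of])
        if dn_mask_logits is not None and gt_masks is not None:
            bce, dice = _mask_terms(dn_mask_logits[pos], np.asarray(gt_masks)[gt_of])
    l_box = weights.w_l1 * l1 + weights.w_giou * gi
    l_mask = weights.w_bce * bce + weights.w_dice * dice
    total = weights.lam_cls * l_cls + weights.lam_box * l_box + weights.lam_mask * l_mask
    return total, {"L_cls": l_cls.item(), "L_box": l_box.item(), "L_mask": l_mask.item()}
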