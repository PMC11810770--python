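"""Confidence-aware COCO-style evaluation of instance segmentations.

Average precision is computed per IoU threshold over the grid 0.50-0.90 in
steps of 0.05 (nine values): predictions are swept in descending confidence
order, each greedily matched to the best still-unmatched ground-truth mask,
counted as a true positive when that IoU exceeds the threshold (strict >, with
a flag for >=), and AP is the 101-point interpolation of the resulting
precision-recall curve.  With multiple classes, mAP is the mean of per-class
APs.  Methods without confidence output are handled by the convention of
assigning every prediction a score of 1.

The calibration curve measures classification accuracy among predictions
matched to ground truth at IoU 0.5, as a function of a confidence-score
cutoff, summarized by the ordinary-least-squares slope of accuracy on cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import InstanceRecord, ValidationError

__all__ = ["EvalConfig", "EvalResult", "mask_iou", "nms", "average_precision",
           "evaluate", "calibration_curve", "DEFAULT_IOU_GRID"]

DEFAULT_IOU_GRID = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))


@dataclass
class EvalConfig:
    iou_thresholds: tuple[float, ...] = DEFAULT_IOU_GRID
    nms_iou: float = 0.5
    scoreless_value: float = 1.0       # confidence assigned to score-free methods
    strict_greater: bool = True        # TP requires IoU > t (flag for >=)

    def __post_init__(self):
        t = self.iou_thresholds
        if any(b <= a for a, b in zip(t, t[1:])) or t[0] <= 0 or t[-1] > 1:
            raise ValidationError("iou_thresholds must be strictly increasing in (0, 1]")


@dataclass
class EvalResult:
    ap_per_threshold: dict[float, float]
    mean_ap: float
    per_class: dict[int, dict[float, float]]
    pr_curves: dict = field(default_factory=dict)
    calibration: dict | None = None
    strata: dict[str, float] | None = None


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValidationError("IoU undefined: both masks empty")
    return float(np.logical_and(a, b).sum() / union)


def _sort_order(records: list[InstanceRecord]) -> list[int]:
    """Deterministic ranking: score desc, mask area desc, index asc."""
    return sorted(range(len(records)),
                  key=lambda i: (-records[i].score, -records[i].area, i))


def nms(records: list[InstanceRecord], nms_iou: float = 0.5) -> list[InstanceRecord]:
    """Greedy non-maximum suppression on mask IoU.

    Sweep in descending score order, keep a record unless its mask IoU with an
    already-kept record exceeds `nms_iou`.
    """
    kept: list[InstanceRecord] = []
    for i in _sort_order(records):
        rec = records[i]
        if all(mask_iou(rec.mask, k.mask) <= nms_iou for k in kept):
            kept.append(rec)
    return kept


def _greedy_match(preds: list[tuple[int, InstanceRecord]],
                  gts: list[tuple[int, InstanceRecord]],
                  t: float, strict: bool = True):
    """Score-ordered greedy matching of (image_id, record) predictions to GT.

    Each ground truth is matched at most once.  Returns (tp flags aligned with
    the score ordering, the ordering itself, matched GT index or -1 per pred).
    """
    recs = [r for _, r in preds]
    order = sorted(range(len(preds)), key=lambda i: (-recs[i].score, -recs[i].area, i))
    gt_used = np.zeros(len(gts), dtype=bool)
    gt_by_img: dict[int, list[int]] = {}
    for j, (img, _) in enumerate(gts):
        gt_by_img.setdefault(img, []).append(j)
    tp = np.zeros(len(order), dtype=bool)
    matched_gt = np.full(len(order), -1)
    for rank, i in enumerate(order):
        img, rec = preds[i]
        best_iou, best_j = 0.0, -1
        for j in gt_by_img.get(img, []):
            if gt_used[j]:
                continue
            iou = mask_iou(rec.mask, gts[j][1].mask)
            if iou > best_iou:
                best_iou, best_j = iou, j
        hit = best_iou > t if strict else best_iou >= t
        if hit and best_j >= 0:
            tp[rank] = True
            gt_used[best_j] = True
            matched_gt[rank] = best_j
    return tp, order, matched_gt


def _interp_ap(precision: np.ndarray, recall: np.ndarray) -> float:
    """101-point interpolated AP (COCO convention)."""
    if len(precision) == 0:
        return 0.0
    # precision envelope: max precision at any recall >= r
    prec = precision.copy()
    for i in range(len(prec) - 2, -1, -1):
        prec[i] = max(prec[i], prec[i + 1])
    grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < len(prec), prec[np.minimum(idx, len(prec) - 1)], 0.0)
    return float(vals.mean())


def average_precision(preds: list[tuple[int, InstanceRecord]],
                      gts: list[tuple[int, InstanceRecord]],
                      t: float, strict: bool = True):
    """AP at IoU threshold `t` plus the precision-recall curve.

    `preds`/`gts` are (image_id, record) pairs; matching is within-image.
    Empty GT with nonempty predictions gives AP = 0.
    """
    n_gt = len(gts)
    if not preds:
        return 0.0, (np.array([]), np.array([]))
    if n_gt == 0:
        return 0.0, (np.zeros(len(preds)), np.zeros(len(preds)))
    tp, order, _ = _greedy_match(preds, gts, t, strict)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt
    return _interp_ap(precision, recall), (precision, recall)


def evaluate(preds_by_image: dict[int, list[InstanceRecord]],
             gt_by_image: dict[int, list[InstanceRecord]],
             cfg: EvalConfig | None = None,
             strata: dict[int, str] | None = None,
             apply_nms: bool = True,
             with_calibration: bool = False,
             categories: list[int] | None = None) -> EvalResult:
    """AP per IoU threshold, per class and overall; optional stratified means.

    Multiclass: AP is computed per class (predictions and GT restricted to the
    class) and averaged over the classes present in the ground truth; mean_ap
    additionally averages over the IoU threshold grid.
    """
    cfg = cfg or EvalConfig()
    if apply_nms:
        preds_by_image = {img: nms(rs, cfg.nms_iou) for img, rs in preds_by_image.items()}
    flat_preds = [(img, r) for img, rs in preds_by_image.items() for r in rs]
    flat_gts = [(img, r) for img, rs in gt_by_image.items() for r in rs]
    gt_classes = sorted({r.class_id for _, r in flat_gts})
    pred_classes = {r.class_id for _, r in flat_preds}
    if not gt_classes:
        raise ValidationError("evaluation requires at least one ground-truth instance")
    if categories is not None:
        unknown = pred_classes - set(categories)
        if unknown:
            raise ValidationError(f"predicted classes not in categories: {sorted(unknown)}")
    # predictions of classes absent from the GT do not enter any class curve:
    # per the reference-package convention, AP averages over classes with GT.
    per_class: dict[int, dict[float, float]] = {}
    pr_curves = {}
    for cls in gt_classes:
        p_cls = [(i, r) for i, r in flat_preds if r.class_id == cls]
        g_cls = [(i, r) for i, r in flat_gts if r.class_id == cls]
        per_class[cls] = {}
        for t in cfg.iou_thresholds:
            ap, pr = average_precision(p_cls, g_cls, t, cfg.strict_greater)
            per_class[cls][t] = ap
            pr_curves[(cls, t)] = pr
    ap_per_threshold = {t: float(np.mean([per_class[c][t] for c in gt_classes]))
                        for t in cfg.iou_thresholds}
    mean_ap = float(np.mean(list(ap_per_threshold.values())))
    strata_out = None
    if strata is not None:
        strata_out = {}
        for label in sorted(set(strata.values())):
            imgs = {i for i, s in strata.items() if s == label}
            sub = evaluate({i: preds_by_image.get(i, []) for i in imgs},
                           {i: gt_by_image.get(i, []) for i in imgs},
                           cfg, strata=None, apply_nms=False)
            strata_out[label] = sub.mean_ap
    calib = None
    if with_calibration:
        acc, cuts, slope, pval = calibration_curve(flat_preds, flat_gts)
        calib = {"thresholds": cuts, "accuracy": acc, "slope": slope, "p_value": pval}
    return EvalResult(ap_per_threshold=ap_per_threshold, mean_ap=mean_ap,
                      per_class=per_class, pr_curves=pr_curves,
                      calibration=calib, strata=strata_out)


def calibration_curve(preds: list[tuple[int, InstanceRecord]],
                      gts: list[tuple[int, InstanceRecord]],
                      thresholds: np.ndarray | None = None,
                      match_iou: float = 0.5):
    """Classification accuracy vs confidence cutoff among matched predictions.

    Predictions are matched to ground truth at IoU `match_iou` regardless of
    class; for each cutoff the accuracy (predicted class equals matched GT
    class) is computed over matched predictions with score >= cutoff.  Empty
    cutoff bins are omitted.  Returns (accuracies, cutoffs used, OLS slope,
    slope p-value).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.91, 0.1), 2)
    tp, order, matched_gt = _greedy_match(preds, gts, match_iou, strict=False)
    scores, correct = [], []
    for rank, i in enumerate(order):
        if matched_gt[rank] >= 0:
            _, rec = preds[i]
            gt_rec = gts[matched_gt[rank]][1]
            scores.append(rec.score)
            correct.append(rec.class_id == gt_rec.class_id)
    scores = np.asarray(scores)
    correct = np.asarray(correct, dtype=float)
    accs, cuts = [], []
    for c in thresholds:
        sel = scores >= c
        if sel.any():
            accs.append(float(correct[sel].mean()))
            cuts.append(float(c))
    accs_arr, cuts_arr = np.asarray(accs), np.asarray(cuts)
    if len(accs_arr) < 2 or np.allclose(cuts_arr, cuts_arr[0]):
        return accs_arr, cuts_arr, float("nan"), float("nan")
    fit = stats.linregress(cuts_arr, accs_arr)
    return accs_arr, cuts_arr, float(fit.slope), float(fit.pvalue)
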