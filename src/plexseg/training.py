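"""Training loop with validation-AP early stopping.

An "epoch" is one pass over the training image list.  Every `eval_every`
epochs the model is evaluated on the validation set (mask mAP over the
standard IoU grid); training stops when validation mAP has not improved for
`patience` epochs or when `max_iter` optimizer steps are reached, and the
checkpoint with the best validation mAP is returned.  Fully seeded: data
order and denoising noise derive from the config seed, so two runs with the
same config and data produce bit-identical histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .data import InstanceRecord, MultiplexImage, ValidationError
from .evaluation import EvalConfig, evaluate
from .model import SegmentationModel, infer
from .nn import Adam, clip_grad_norm

__all__ = ["TrainConfig", "TrainResult", "train",
           "finetune_train_config", "xenium_train_config", "merfish_train_config",
           "tiny_train_config"]


@dataclass
class TrainConfig:
    base_lr: float = 1e-4
    batch_size: int = 1            # gradient steps accumulate over this many images
    max_iter: int = 2000
    eval_every: int = 5            # epochs between validation evaluations
    patience: int = 15             # epochs without val-mAP improvement before stopping
    grad_clip: float = 0.1
    score_threshold: float = 0.3   # confidence cutoff during validation inference
    seed: int = 0

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValidationError("base_lr must be positive")
        if self.patience < self.eval_every:
            raise ValidationError("patience must be >= eval_every")


def finetune_train_config(**kw) -> TrainConfig:
    """Fine-tuning protocol: Adam lr 1e-6, batch 8, eval every 5 epochs,
    stop after 15 epochs without validation-AP improvement."""
    return TrainConfig(**{**dict(base_lr=1e-6, batch_size=8, eval_every=5,
                                 patience=15, max_iter=10 ** 9), **kw})


def xenium_train_config(**kw) -> TrainConfig:
    return TrainConfig(**{**dict(base_lr=1e-4, batch_size=16, max_iter=20000,
                                 eval_every=5, patience=15), **kw})


def merfish_train_config(**kw) -> TrainConfig:
    return TrainConfig(**{**dict(base_lr=1e-4, batch_size=16, max_iter=5000,
                                 eval_every=5, patience=15), **kw})


def tiny_train_config(**kw) -> TrainConfig:
    """From-scratch desk-scale protocol (no pretrained weights to fine-tune)."""
    return TrainConfig(**{**dict(base_lr=1e-3, batch_size=1, max_iter=2000,
                                 eval_every=5, patience=50), **kw})


@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)       # per-iteration loss records
    val_history: list[dict] = field(default_factory=list)   # per-evaluation mAP records
    best_state: dict | None = None
    best_map: float = -1.0
    n_iter: int = 0


Sample = tuple[MultiplexImage, list[InstanceRecord]]


def _val_map(model: SegmentationModel, val: list[Sample], cfg: TrainConfig) -> float:
    preds = {}
    gts = {}
    for i, (img, gt) in enumerate(val):
        preds[i] = infer(model, img, score_threshold=cfg.score_threshold)
        gts[i] = gt
    if not any(gts.values()):
        return 0.0
    return evaluate(preds, gts, EvalConfig()).mean_ap


def train(model: SegmentationModel, train_set: list[Sample], val_set: list[Sample],
          cfg: TrainConfig, evaluator=None, log_every: int = 50) -> TrainResult:
    """Optimize `model`; returns history and the best-validation checkpoint.

    `evaluator` overrides the validation metric (signature: model -> float);
    used by tests to stub the early-stopping schedule.
    """
    if not train_set or not val_set:
        raise ValidationError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.base_lr)
    result = TrainResult()
    it = 0
    epoch = 0
    best_epoch = 0
    stop = False
    while not stop:
        epoch += 1
        order = rng.permutation(len(train_set))
        pending = 0
        for k in order:
            img, gt = train_set[int(k)]
            loss, bd = model.training_loss(img, gt, noise_rng=rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at iteration {it}")
            loss.backward(np.array(1.0 / cfg.batch_size))
            pending += 1
            if pending >= cfg.batch_size:
                it += 1
                clip_grad_norm(model.parameters(), cfg.grad_clip)
                opt.step()
                opt.zero_grad()
                pending = 0
                if it == 1 or it % log_every == 0 or it == cfg.max_iter:
                    result.history.append({"iter": it, "epoch": epoch,
                                           "loss": float(bd["total"])})
                if it >= cfg.max_iter:
                    stop = True
                    break
        if epoch % cfg.eval_every == 0 or stop:
            val = float(evaluator(model)) if evaluator is not None \
                else _val_map(model, val_set, cfg)
            result.val_history.append({"epoch": epoch, "iter": it, "map": val})
            if val > result.best_map:
                result.best_map = val
                result.best_state = copy.deepcopy(model.state_dict())
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.patience:
                stop = True
        result.n_iter = it
    if result.best_state is None:
        result.best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(result.best_state)
    return result
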