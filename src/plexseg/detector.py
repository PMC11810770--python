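"""Detection-and-classification module (DINO-style set prediction).

Pipeline: flatten the multiscale feature pyramid into tokens fused with
sinusoidal positional and learned level embeddings; run a transformer encoder
to obtain latent features C_e; select the top-n tokens by class-agnostic
objectness to initialize positional queries (anchor boxes) while content
queries stay learnable ("mixed query selection"); refine anchors iteratively
through decoder layers (dense or deformable cross-attention); and classify
each query with a linear head over K object classes plus a "no object" slot.

Contrastive denoising training adds, per ground-truth box and denoising
group, one positive query perturbed within the small-noise bounds
|dx| < lam1*w/2, |dy| < lam1*h/2, |dw| < lam1*w, |dh| < lam1*h and one
negative query whose per-coordinate perturbation lies in the (lam1, lam2]
annulus, with an attention mask isolating denoising groups from each other
and from the matching queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concatenate
from .backbone import FeaturePyramid
from .data import InstanceRecord, ValidationError
from .nn import (Linear, LayerNorm, MLP, Module, MultiheadAttention, Parameter,
                 grid_sample_points, sinusoidal_embedding_2d)

__all__ = ["DetectorConfig", "NoiseConfig", "EncoderMemory", "QuerySet", "DenoiseBlock",
           "DINODetector", "make_denoising_queries", "classify",
           "inverse_sigmoid", "sigmoid_np"]


def sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-x))


def inverse_sigmoid(p, eps=1e-5):
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


@dataclass
class DetectorConfig:
    d_model: int = 32
    n_heads: int = 4
    n_encoder_layers: int = 1
    n_decoder_layers: int = 2
    n_queries: int = 1000           # queries should exceed the per-image instance count
    n_classes: int = 1              # K object classes (a K+1-th "no object" slot is added)
    ffn_ratio: float = 2.0
    attention: str = "dense"        # "dense" | "deformable"
    n_points: int = 4               # sampling points per head and level (deformable)
    pos_temperature: float = 10000.0
    max_tokens: int = 40000
    label_flip_prob: float = 0.2    # denoising label noise
    n_denoise_groups: int = 5

    def __post_init__(self):
        if self.attention not in ("dense", "deformable"):
            raise ValidationError(f"unknown attention mode {self.attention!r}")
        if self.n_queries <= 0:
            raise ValidationError("n_queries must be positive")


@dataclass
class NoiseConfig:
    lam1: float = 0.4
    lam2: float = 1.0
    n_groups: int = 5
    label_flip_prob: float = 0.2

    def __post_init__(self):
        if not (0 < self.lam1 < self.lam2):
            raise ValidationError("need 0 < lam1 < lam2")


@dataclass
class EncoderMemory:
    """Flattened multiscale tokens before (X) and after (C_e) the encoder."""

    X: Tensor                       # (L_tokens, d) features + positional embeddings
    C_e: Tensor                     # (L_tokens, d) encoder output
    pos: np.ndarray                 # (L_tokens, d) positional embedding alone
    level_index: np.ndarray         # (L_tokens, 3) rows of (stride, row, col)
    level_shapes: list[tuple[int, int, int]]   # (stride, h, w) per level
    centers: np.ndarray             # (L_tokens, 2) normalized (cx, cy) token centers
    base_wh: np.ndarray             # (L_tokens, 2) normalized default anchor (w, h)

    @property
    def n_tokens(self) -> int:
        return self.X.shape[0]


@dataclass
class QuerySet:
    """Positional (anchor-box) and content queries for the decoder."""

    q_pos_logit: np.ndarray         # (n, 4) anchors as inverse-sigmoid logits
    q_content: Tensor               # (n, d) learnable content embeddings
    enc_proposals: Tensor           # (L_tokens, 4) encoder-stage box proposals (normalized)
    enc_logits: Tensor              # (L_tokens, K+1) encoder-stage class logits
    top_idx: np.ndarray             # (n,) selected token indices
    objectness: np.ndarray          # (L_tokens,) selection scores

    @property
    def n(self) -> int:
        return self.q_pos_logit.shape[0]

    @property
    def q_pos(self) -> np.ndarray:
        return sigmoid_np(self.q_pos_logit)


@dataclass
class DenoiseBlock:
    boxes_logit: np.ndarray         # (n_dn, 4) noised GT boxes, logit space
    labels: np.ndarray              # (n_dn,) noised labels in [0, K-1]
    gt_index: np.ndarray            # (n_dn,) index of the originating GT instance
    group: np.ndarray               # (n_dn,) denoising group id
    positive: np.ndarray            # (n_dn,) bool, True for small-noise queries
    deltas: np.ndarray              # (n_dn, 4) raw (dx, dy, dw, dh) perturbations

    @property
    def n(self) -> int:
        return len(self.labels)

    @staticmethod
    def empty() -> "DenoiseBlock":
        z = np.zeros((0,))
        return DenoiseBlock(np.zeros((0, 4)), z.astype(int), z.astype(int),
                            z.astype(int), z.astype(bool), np.zeros((0, 4)))


@dataclass
class DecoderOutput:
    boxes_per_layer: list[Tensor]   # each (N, 4) normalized cxcywh
    logits_per_layer: list[Tensor]  # each (N, K+1)
    q_c: Tensor                     # (N, d) final content embeddings
    n_match: int                    # leading n_match rows are matching queries

    def matching(self, arr_list_idx: int = -1):
        return (self.boxes_per_layer[arr_list_idx][:self.n_match],
                self.logits_per_layer[arr_list_idx][:self.n_match],
                self.q_c[:self.n_match])


# ---------------------------------------------------------------- operations

def make_denoising_queries(gt: list[InstanceRecord], noise: NoiseConfig, K: int,
                           rng: np.random.Generator, image_hw: tuple[int, int],
                           max_total: int | None = None) -> DenoiseBlock:
    """Contrastive denoising queries from ground truth.

    Positive perturbations satisfy all four lam1 inequalities strictly;
    negative perturbations lie per-coordinate in the (lam1, lam2] annulus, so
    they satisfy the lam2 bounds while violating the lam1 bounds.
    """
    if not gt:
        return DenoiseBlock.empty()
    H, W = image_hw
    boxes = np.stack([inst.box.to_normalized(H, W).as_array() for inst in gt])
    n_gt = len(gt)
    n_groups = noise.n_groups
    if max_total is not None:
        n_groups = max(1, min(n_groups, max_total // max(1, 2 * n_gt)))
    rows_box, rows_lab, rows_gt, rows_grp, rows_pos, rows_delta = [], [], [], [], [], []
    for g in range(n_groups):
        for positive in (True, False):
            w, h = boxes[:, 2], boxes[:, 3]
            half = np.stack([w / 2, h / 2, w, h], axis=1)    # lam-bound scales
            if positive:
                u = rng.uniform(-1.0, 1.0, size=(n_gt, 4))
                u = np.clip(u, -1 + 1e-9, 1 - 1e-9)          # keep bounds strict
                delta = u * noise.lam1 * half
            else:
                mag = rng.uniform(noise.lam1, noise.lam2, size=(n_gt, 4))
                sign = rng.choice([-1.0, 1.0], size=(n_gt, 4))
                delta = sign * mag * half
            noised = boxes + delta
            noised[:, :2] = np.clip(noised[:, :2], 1e-4, 1 - 1e-4)
            noised[:, 2:] = np.clip(noised[:, 2:], 1e-4, 1.0)
            labels = np.array([inst.class_id for inst in gt])
            if K > 1 and noise.label_flip_prob > 0:
                flip = rng.uniform(size=n_gt) < noise.label_flip_prob
                shift = rng.integers(1, K, size=n_gt)
                labels = np.where(flip, (labels + shift) % K, labels)
            rows_box.append(inverse_sigmoid(noised))
            rows_lab.append(labels)
            rows_gt.append(np.arange(n_gt))
            rows_grp.append(np.full(n_gt, g))
            rows_pos.append(np.full(n_gt, positive))
            rows_delta.append(delta)
    return DenoiseBlock(
        boxes_logit=np.concatenate(rows_box),
        labels=np.concatenate(rows_lab).astype(int),
        gt_index=np.concatenate(rows_gt),
        group=np.concatenate(rows_grp),
        positive=np.concatenate(rows_pos),
        deltas=np.concatenate(rows_delta))


def denoise_attention_mask(n_match: int, block: DenoiseBlock) -> np.ndarray | None:
    """Additive self-attention mask: matching queries and denoising groups are
    mutually isolated (no ground-truth leakage into the matching path)."""
    if block.n == 0:
        return None
    N = n_match + block.n
    allow = np.zeros((N, N), dtype=bool)
    allow[:n_match, :n_match] = True
    grp = block.group
    same = grp[:, None] == grp[None, :]
    allow[n_match:, n_match:] = same
    return np.where(allow, 0.0, -1e9)


def classify(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Softmax class probabilities, argmax object class, confidence score.

    Z has shape (..., K+1); the last slot is "no object".  The confidence is
    the maximum class probability excluding the "no object" slot.  Stable
    under a constant shift of the logits.
    """
    Z = np.asarray(Z, dtype=np.float64)
    z = Z - Z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    obj = probs[..., :-1]
    pred = obj.argmax(axis=-1)
    score = obj.max(axis=-1)
    return probs, pred, score


# ------------------------------------------------------------------- modules

class EncoderLayer(Module):
    def __init__(self, d: int, n_heads: int, ffn_ratio: float, rng):
        self.norm1 = LayerNorm(d)
        self.attn = MultiheadAttention(d, n_heads, rng)
        self.norm2 = LayerNorm(d)
        hidden = int(d * ffn_ratio)
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor, pos: np.ndarray) -> Tensor:
        h = self.norm1(x)
        hp = h + Tensor(pos)
        x = x + self.attn(hp, hp, h)
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class DeformableCrossAttention(Module):
    """Learned sampling of n_points per head and level with bilinear
    interpolation, attention weights softmax-normalized over (level, point)."""

    def __init__(self, d: int, n_heads: int, n_levels: int, n_points: int, rng):
        self.value_proj = Linear(d, d, rng)
        self.offset_head = Linear(d, n_heads * n_levels * n_points * 2, rng)
        self.weight_head = Linear(d, n_heads * n_levels * n_points, rng)
        self.out_proj = Linear(d, d, rng)
        # start with near-zero offsets so early training samples at the anchor
        self.offset_head.weight.data *= 0.01
        self._h, self._L, self._P = n_heads, n_levels, n_points

    def __call__(self, q: Tensor, memory: EncoderMemory, anchors: np.ndarray) -> Tensor:
        h, L, P = self._h, self._L, self._P
        N, d = q.shape
        dh = d // h
        vals = self.value_proj(memory.C_e)                 # (T, d)
        offsets = self.offset_head(q).reshape(N, h, L, P, 2)
        weights = self.weight_head(q).reshape(N, h, L * P).softmax(axis=-1).reshape(N, h, L, P)
        cx, cy, bw, bh = anchors[:, 0], anchors[:, 1], anchors[:, 2], anchors[:, 3]
        out_heads = []
        tok0 = 0
        lvl_contrib = []
        for li, (stride, hh, ww) in enumerate(memory.level_shapes):
            grid = vals[tok0:tok0 + hh * ww].reshape(hh, ww, d)
            tok0 += hh * ww
            # sample location = anchor center + offset scaled by anchor size, in
            # this level's pixel units (half-pixel centers)
            base_r = Tensor(cy[:, None, None] * hh - 0.5)
            base_c = Tensor(cx[:, None, None] * ww - 0.5)
            off = offsets[:, :, li]                       # (N, h, P, 2) Tensor
            locr = off[:, :, :, 0] * Tensor(bh[:, None, None] * hh) + base_r
            locc = off[:, :, :, 1] * Tensor(bw[:, None, None] * ww) + base_c
            from .autograd import stack as tstack
            locs = tstack([locr, locc], axis=-1)          # (N, h, P, 2)
            sampled = grid_sample_points(grid, locs)      # (N, h, P, d)
            w_lvl = weights[:, :, li]                     # (N, h, P)
            contrib = (sampled * w_lvl.reshape(N, h, P, 1)).sum(axis=2)  # (N, h, d)
            lvl_contrib.append(contrib)
        total = lvl_contrib[0]
        for c in lvl_contrib[1:]:
            total = total + c
        # per-head slice of the value dimension, then concatenate
        parts = [total[:, i, i * dh:(i + 1) * dh] for i in range(h)]
        out = concatenate(parts, axis=-1)
        return self.out_proj(out)


class DecoderLayer(Module):
    def __init__(self, cfg: DetectorConfig, n_levels: int, rng):
        d = cfg.d_model
        self.norm_sa = LayerNorm(d)
        self.self_attn = MultiheadAttention(d, cfg.n_heads, rng)
        self.norm_ca = LayerNorm(d)
        if cfg.attention == "dense":
            self.cross_attn = MultiheadAttention(d, cfg.n_heads, rng)
        else:
            self.cross_attn = DeformableCrossAttention(d, cfg.n_heads, n_levels,
                                                       cfg.n_points, rng)
        self.norm_ffn = LayerNorm(d)
        hidden = int(d * cfg.ffn_ratio)
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)
        self._dense = cfg.attention == "dense"

    def __call__(self, x: Tensor, qpos: Tensor, memory: EncoderMemory,
                 anchors: np.ndarray, attn_mask: np.ndarray | None) -> Tensor:
        h = self.norm_sa(x)
        hq = h + qpos
        x = x + self.self_attn(hq, hq, h, attn_mask=attn_mask)
        h = self.norm_ca(x)
        if self._dense:
            mem = memory.C_e + Tensor(memory.pos)
            x = x + self.cross_attn(h + qpos, mem, memory.C_e)
        else:
            x = x + self.cross_attn(h + qpos, memory, anchors)
        return x + self.fc2(self.fc1(self.norm_ffn(x)).gelu())


class DINODetector(Module):
    def __init__(self, cfg: DetectorConfig, level_dims: list[tuple[int, int]],
                 rng: np.random.Generator):
        """level_dims: list of (stride, channel dim) of the pyramid levels fed
        to the detector, ascending stride."""
        self.cfg = cfg
        d = cfg.d_model
        self.input_proj = [Linear(dim, d, rng) for _, dim in level_dims]
        self.level_embed = Parameter(rng.normal(0, 0.02, size=(len(level_dims), d)))
        self.enc_layers = [EncoderLayer(d, cfg.n_heads, cfg.ffn_ratio, rng)
                           for _ in range(cfg.n_encoder_layers)]
        self.enc_box_head = MLP(d, d, 4, 3, rng)
        self.query_content = Parameter(rng.normal(0, 0.02, size=(cfg.n_queries, d)))
        self.label_embed = Parameter(rng.normal(0, 0.02, size=(cfg.n_classes + 1, d)))
        self.ref_point_head = MLP(d, d, d, 2, rng)
        self.dec_layers = [DecoderLayer(cfg, len(level_dims), rng)
                           for _ in range(cfg.n_decoder_layers)]
        self.box_head = MLP(d, d, 4, 3, rng)
        # final box delta starts at zero: refinement identity at initialization
        self.box_head.layers[-1].weight.data[:] = 0.0
        self.box_head.layers[-1].bias.data[:] = 0.0
        self.class_head = Linear(d, cfg.n_classes + 1, rng)
        self._strides = [s for s, _ in level_dims]

    # -- encoder ------------------------------------------------------------
    def encode(self, pyramid: FeaturePyramid) -> EncoderMemory:
        """Flatten the pyramid, fuse positional/level embeddings, run encoder."""
        cfg = self.cfg
        toks, pos_rows, idx_rows, shapes, centers, base_wh = [], [], [], [], [], []
        used = [(s, f) for s, f in pyramid.levels if s in self._strides]
        if not used:
            raise ValidationError("feature pyramid contains no configured detector stride")
        for li, (stride, feat) in enumerate(used):
            D, h, w = feat.shape
            t = feat.reshape(D, h * w).transpose(1, 0)
            t = self.input_proj[li](t)
            rr, cc = np.divmod(np.arange(h * w), w)
            cy = (rr + 0.5) / h
            cx = (cc + 0.5) / w
            pe = sinusoidal_embedding_2d(cy, cx, cfg.d_model, cfg.pos_temperature)
            pe = pe + self.level_embed.data[li]
            toks.append(t)
            pos_rows.append(pe)
            idx_rows.append(np.stack([np.full(h * w, stride), rr, cc], axis=1))
            shapes.append((stride, h, w))
            centers.append(np.stack([cx, cy], axis=1))
            base_wh.append(np.full((h * w, 2), [6.0 / w, 6.0 / h]))
        X_feat = concatenate(toks, axis=0)
        pos = np.concatenate(pos_rows)
        if X_feat.shape[0] > cfg.max_tokens:
            raise ValidationError(f"token count {X_feat.shape[0]} exceeds budget {cfg.max_tokens}")
        X = X_feat + Tensor(pos)
        h = X_feat
        for layer in self.enc_layers:
            h = layer(h, pos)
        return EncoderMemory(X=X, C_e=h, pos=pos,
                             level_index=np.concatenate(idx_rows),
                             level_shapes=shapes,
                             centers=np.concatenate(centers),
                             base_wh=np.concatenate(base_wh))

    # -- mixed query selection ----------------------------------------------
    def select_queries(self, memory: EncoderMemory, n: int | None = None) -> QuerySet:
        """Top-n tokens by objectness initialize anchors; content stays learnable.

        Objectness is the maximum object-class logit of the shared class head
        applied to the encoder tokens; anchors come from the encoder box head
        applied on top of each token's default anchor.
        """
        cfg = self.cfg
        if n is None:
            n = cfg.n_queries
        if n <= 0:
            raise ValidationError("query count must be positive")
        T = memory.n_tokens
        n_eff = min(n, T)
        enc_logits = self.class_head(memory.C_e)             # (T, K+1)
        objectness = enc_logits.data[:, :-1].max(axis=-1)
        ref = np.concatenate([memory.centers, memory.base_wh], axis=1)
        delta = self.enc_box_head(memory.C_e)
        proposals = (delta + Tensor(inverse_sigmoid(ref))).sigmoid()   # (T, 4)
        top = np.argsort(-objectness, kind="stable")[:n_eff]
        q_pos_logit = inverse_sigmoid(proposals.data[top])   # detached anchor init
        q_content = self.query_content[:n_eff]
        return QuerySet(q_pos_logit=q_pos_logit, q_content=q_content,
                        enc_proposals=proposals, enc_logits=enc_logits,
                        top_idx=top, objectness=objectness)

    # -- decoder --------------------------------------------------------------
    def decode(self, memory: EncoderMemory, queries: QuerySet,
               denoise: DenoiseBlock | None = None) -> DecoderOutput:
        """Iterative anchor refinement; returns per-layer boxes and logits.

        The returned arrays stack matching queries first, then denoising
        queries; self-attention is masked so that matching queries and
        denoising groups never exchange information.
        """
        cfg = self.cfg
        denoise = denoise if denoise is not None else DenoiseBlock.empty()
        n_match = queries.n
        anchors_logit = np.concatenate([queries.q_pos_logit, denoise.boxes_logit])
        content = queries.q_content
        if denoise.n:
            dn_content = self.label_embed[denoise.labels]
            content = concatenate([content, dn_content], axis=0)
        attn_mask = denoise_attention_mask(n_match, denoise)
        boxes_per_layer, logits_per_layer = [], []
        x = content
        for layer in self.dec_layers:
            anchors = sigmoid_np(anchors_logit)
            pe = sinusoidal_embedding_2d(anchors[:, 1], anchors[:, 0],
                                         cfg.d_model, cfg.pos_temperature)
            qpos = self.ref_point_head(Tensor(pe))
            x = layer(x, qpos, memory, anchors, attn_mask)
            if not np.all(np.isfinite(x.data)):
                raise FloatingPointError(
                    f"non-finite decoder activation at layer {len(boxes_per_layer)}")
            delta = self.box_head(x)
            boxes = (delta + Tensor(anchors_logit)).sigmoid()
            boxes_per_layer.append(boxes)
            logits_per_layer.append(self.class_head(x))
            anchors_logit = inverse_sigmoid(boxes.data)      # detached propagation
        return DecoderOutput(boxes_per_layer=boxes_per_layer,
                             logits_per_layer=logits_per_layer,
                             q_c=x, n_match=n_match)
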