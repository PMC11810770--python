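"""Segmentation branch: per-pixel embeddings and per-query mask prediction.

The pixel embedding map is E = M(T(C_b) + F(C_e)): T projects the stride-4
backbone level to the transformer hidden dimension with a 1x1 convolution,
F bilinearly upsamples the encoder latent tokens (reshaped to their spatial
grids) to the same resolution, and M is a small convolutional segmentation
head.  Each query's mask logit grid is the spatial dot product of its content
embedding q_c with E, so mask prediction is exactly linear in q_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .backbone import FeaturePyramid
from .data import ValidationError, mask_to_box
from .detector import EncoderMemory, inverse_sigmoid
from .nn import Conv2d, Linear, Module, resize_bilinear

__all__ = ["MaskHeadConfig", "PixelEmbeddingMap", "MaskHead",
           "predict_masks", "binarize_masks", "upsample_mask_logits",
           "unified_query_init_from_masks"]


@dataclass
class MaskHeadConfig:
    stride: int = 4          # pyramid level feeding the pixel map
    hidden_dim: int = 32     # transformer hidden dimension D
    conv_depth: int = 3      # layers in the segmentation head M
    threshold: float = 0.5   # sigmoid binarization threshold


@dataclass
class PixelEmbeddingMap:
    """D x H' x W' per-pixel embedding grid at the mask-head stride."""

    E: Tensor
    stride: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.E.data)):
            raise ValidationError("pixel embedding map contains non-finite values")


class MaskHead(Module):
    def __init__(self, cfg: MaskHeadConfig, backbone_dim: int, rng: np.random.Generator):
        self.cfg = cfg
        D = cfg.hidden_dim
        self.t_proj = Conv2d(backbone_dim, D, kernel=1, rng=rng)          # T
        self.f_proj = Linear(D, D, rng)                                   # applied before F
        self.m_convs = [Conv2d(D, D, kernel=3, rng=rng, padding=1)        # M
                        for _ in range(cfg.conv_depth)]

    def build_pixel_map(self, c_b: FeaturePyramid, c_e: EncoderMemory) -> PixelEmbeddingMap:
        """E = M(T(C_b) + F(C_e)); deterministic in eval mode."""
        cfg = self.cfg
        base = self.t_proj(c_b.level(cfg.stride))         # (D, H', W')
        D, Hm, Wm = base.shape
        x = base
        tok0 = 0
        proj = self.f_proj(c_e.C_e)
        for stride, h, w in c_e.level_shapes:
            grid = proj[tok0:tok0 + h * w].reshape(h, w, D).transpose(2, 0, 1)
            tok0 += h * w
            up = resize_bilinear(grid, (Hm, Wm))
            assert up.shape == (D, Hm, Wm)
            x = x + up
        for i, conv in enumerate(self.m_convs):
            x = conv(x)
            if i < len(self.m_convs) - 1:
                x = x.gelu()
        return PixelEmbeddingMap(E=x, stride=cfg.stride)


def predict_masks(q_c: Tensor, emap: PixelEmbeddingMap | Tensor) -> Tensor:
    """Per-query mask logits: spatial dot product of q_c with the pixel map.

    q_c: (N, D); returns (N, H', W') logits at the mask-head stride.
    """
    E = emap.E if isinstance(emap, PixelEmbeddingMap) else emap
    D, H, W = E.shape
    if q_c.shape[-1] != D:
        raise ValidationError(f"query dim {q_c.shape[-1]} != pixel embedding dim {D}")
    flat = E.reshape(D, H * W)
    return (q_c @ flat).reshape(q_c.shape[0], H, W)


def upsample_mask_logits(logits: Tensor | np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinearly upsample (N, H', W') logits to image resolution (no grad)."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    return resize_bilinear(Tensor(arr), out_hw).data


def binarize_masks(logits: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sigmoid + threshold; threshold 0.5 on probability = 0 on the logit."""
    cut = np.log(threshold / (1 - threshold))
    return np.asarray(logits) > cut


def unified_query_init_from_masks(mask_logits: np.ndarray, anchors_logit: np.ndarray,
                                  threshold: float = 0.5) -> np.ndarray:
    """Replace anchors by tight boxes of the binarized initial masks.

    Masks come from the encoder-stage proposals; queries whose initial mask is
    empty keep their original anchor.  Returns anchors in logit space.
    """
    out = anchors_logit.copy()
    binary = binarize_masks(mask_logits, threshold)
    n, Hm, Wm = binary.shape
    for i in range(n):
        if binary[i].any():
            b = mask_to_box(binary[i]).to_normalized(Hm, Wm)
            out[i] = inverse_sigmoid(b.as_array())
    return out
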