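"""Hierarchical windowed-attention feature extractor.

A Swin-style transformer: patch embedding at stride 4, stages of (optionally
shifted) window self-attention blocks with channel width doubling between
stages, and a feature pyramid of the requested strides as output.  The first
layer accepts an arbitrary number of input channels, since multiplexed images
carry anywhere from 1 to 64 markers — there is no 3-channel assumption.

Images are reflect-padded to the required stride/window multiple and the
output levels are cropped back, so arbitrary patch sizes are usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .data import MultiplexImage, ValidationError
from .nn import Conv2d, LayerNorm, Linear, Module, MultiheadAttention

__all__ = ["BackboneConfig", "FeaturePyramid", "SwinBackbone", "extract_features",
           "default_tiny_config", "default_large_config"]


@dataclass
class BackboneConfig:
    in_channels: int = 2
    embed_dim: int = 32
    depths: tuple[int, ...] = (2, 2)
    num_heads: tuple[int, ...] = (2, 4)
    window: int = 4
    out_strides: tuple[int, ...] = (4, 8)
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if len(self.depths) != len(self.num_heads):
            raise ValidationError("depths and num_heads must have equal length")
        if self.window < 2:
            raise ValidationError("window must be >= 2")
        strides = list(self.out_strides)
        if strides != sorted(strides) or any(s & (s - 1) for s in strides):
            raise ValidationError("out_strides must be ascending powers of 2")
        max_stride = 4 * 2 ** (len(self.depths) - 1)
        for s in strides:
            if s < 4 or s > max_stride:
                raise ValidationError(f"stride {s} outside available range 4..{max_stride}")

    def stage_dim(self, stage: int) -> int:
        return self.embed_dim * 2 ** stage


@dataclass
class FeaturePyramid:
    """Multiscale feature maps: list of (stride, D x H/stride x W/stride)."""

    levels: list[tuple[int, Tensor]] = field(default_factory=list)

    def level(self, stride: int) -> Tensor:
        for s, feat in self.levels:
            if s == stride:
                return feat
        raise KeyError(f"no pyramid level at stride {stride}")

    @property
    def strides(self) -> list[int]:
        return [s for s, _ in self.levels]


def default_tiny_config(in_channels: int = 2) -> BackboneConfig:
    """CPU-friendly configuration for tests and small experiments."""
    return BackboneConfig(in_channels=in_channels, embed_dim=32, depths=(2, 2),
                          num_heads=(2, 4), window=4, out_strides=(4, 8))


def default_large_config(in_channels: int = 2) -> BackboneConfig:
    """Large configuration (Swin-L capacity); pretrained weights not bundled."""
    return BackboneConfig(in_channels=in_channels, embed_dim=192,
                          depths=(2, 2, 18, 2), num_heads=(6, 12, 24, 48),
                          window=7, out_strides=(4, 8, 16, 32), mlp_ratio=4.0)


# ------------------------------------------------------------------- modules

def _window_partition(x: Tensor, w: int) -> Tensor:
    """(H, W, D) -> (n_windows, w*w, D)."""
    H, W, D = x.shape
    x = x.reshape(H // w, w, W // w, w, D).transpose(0, 2, 1, 3, 4)
    return x.reshape((H // w) * (W // w), w * w, D)


def _window_merge(x: Tensor, H: int, W: int, w: int) -> Tensor:
    D = x.shape[-1]
    x = x.reshape(H // w, W // w, w, w, D).transpose(0, 2, 1, 3, 4)
    return x.reshape(H, W, D)


def _shift_attn_mask(H: int, W: int, w: int, shift: int) -> np.ndarray:
    """Additive mask blocking attention across wrapped regions after a roll."""
    ids = np.zeros((H, W), dtype=int)
    cnt = 0
    for hs in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
        for ws in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
            ids[hs, ws] = cnt
            cnt += 1
    ids = ids.reshape(H // w, w, W // w, w).transpose(0, 2, 1, 3).reshape(-1, w * w)
    diff = ids[:, :, None] != ids[:, None, :]
    return np.where(diff, -1e9, 0.0)[:, None, :, :]  # (nW, 1 head dim, ww, ww)


class SwinBlock(Module):
    def __init__(self, dim: int, n_heads: int, window: int, shift: int, mlp_ratio: float, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self._window, self._shift = window, shift

    def __call__(self, x: Tensor) -> Tensor:
        H, W, D = x.shape
        w, shift = self._window, self._shift
        shortcut = x
        x = self.norm1(x)
        mask = None
        if shift:
            x = x.roll((-shift, -shift), axis=(0, 1))
            mask = _shift_attn_mask(H, W, w, shift)
        xw = _window_partition(x, w)
        xw = self.attn(xw, xw, xw, attn_mask=mask)
        x = _window_merge(xw, H, W, w)
        if shift:
            x = x.roll((shift, shift), axis=(0, 1))
        x = shortcut + x
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class PatchMerging(Module):
    """2x2 spatial concatenation followed by linear reduction to 2*dim."""

    def __init__(self, dim: int, rng):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        H, W, D = x.shape
        x = x.reshape(H // 2, 2, W // 2, 2, D).transpose(0, 2, 1, 3, 4)
        x = x.reshape(H // 2, W // 2, 4 * D)
        return self.reduce(self.norm(x))


class SwinBackbone(Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.patch_embed = Conv2d(cfg.in_channels, cfg.embed_dim, kernel=4, rng=rng, stride=4)
        self.embed_norm = LayerNorm(cfg.embed_dim)
        self.stages = []
        self.merges = []
        self.out_norms = []
        for s, (depth, heads) in enumerate(zip(cfg.depths, cfg.num_heads)):
            dim = cfg.stage_dim(s)
            blocks = [SwinBlock(dim, heads, cfg.window,
                                shift=(cfg.window // 2) if (b % 2) else 0,
                                mlp_ratio=cfg.mlp_ratio, rng=rng)
                      for b in range(depth)]
            self.stages.append(blocks)
            if s < len(cfg.depths) - 1:
                self.merges.append(PatchMerging(dim, rng))
            self.out_norms.append(LayerNorm(dim))

    # stages is a list of lists; flatten for parameter discovery
    def named_parameters(self, prefix: str = ""):
        yield from self.patch_embed.named_parameters(prefix + "patch_embed.")
        yield from self.embed_norm.named_parameters(prefix + "embed_norm.")
        for s, blocks in enumerate(self.stages):
            for b, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}stages.{s}.{b}.")
        for i, m in enumerate(self.merges):
            yield from m.named_parameters(f"{prefix}merges.{i}.")
        for i, m in enumerate(self.out_norms):
            yield from m.named_parameters(f"{prefix}out_norms.{i}.")

    def __call__(self, image: MultiplexImage) -> FeaturePyramid:
        cfg = self.cfg
        if image.shape[0] != cfg.in_channels:
            raise ValidationError(
                f"image has {image.shape[0]} channels, backbone expects {cfg.in_channels}")
        H, W = image.height, image.width
        unit = 4 * cfg.window * 2 ** (len(cfg.depths) - 1)
        Hp = int(np.ceil(H / unit)) * unit
        Wp = int(np.ceil(W / unit)) * unit
        px = image.pixels
        if (Hp, Wp) != (H, W):
            px = np.pad(px, ((0, 0), (0, Hp - H), (0, Wp - W)), mode="reflect")
        x = self.patch_embed(Tensor(px))             # (D, Hp/4, Wp/4)
        x = x.transpose(1, 2, 0)                     # (h, w, D)
        x = self.embed_norm(x)
        levels = []
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            stride = 4 * 2 ** s
            if stride in cfg.out_strides:
                feat = self.out_norms[s](x).transpose(2, 0, 1)  # (D, h, w)
                hs = int(np.ceil(H / stride))
                ws = int(np.ceil(W / stride))
                levels.append((stride, feat[:, :hs, :ws]))
            if s < len(self.stages) - 1:
                x = self.merges[s](x)
        return FeaturePyramid(levels=levels)


def extract_features(image: MultiplexImage, backbone: SwinBackbone) -> FeaturePyramid:
    """Run the feature extractor; deterministic given weights and input."""
    return backbone(image)
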