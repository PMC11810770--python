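"""Neural-network building blocks over the autograd engine.

Modules hold :class:`Parameter` tensors and are discovered recursively for
optimization and (de)serialization.  Weight initialization is explicit: every
module takes a ``numpy.random.Generator`` so whole models are reproducible
from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "MLP", "MultiheadAttention",
    "Conv2d", "upsample_bilinear", "resize_bilinear", "grid_sample_points",
    "sinusoidal_embedding_2d", "Adam", "clip_grad_norm",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: children are attributes or lists of modules."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self._eps).sqrt() * self.gamma + self.beta


class MLP(Module):
    """Stack of linear layers with GELU between (none after the last)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, n_layers: int, rng):
        dims = [d_in] + [d_hidden] * (n_layers - 1) + [d_out]
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(n_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.gelu()
        return x


class MultiheadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self._h = n_heads
        self._dh = dim // n_heads

    def __call__(self, q: Tensor, k: Tensor, v: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        """q: (..., Nq, D), k/v: (..., Nk, D); attn_mask additive, broadcast to (h, Nq, Nk)."""
        h, dh = self._h, self._dh
        Nq, Nk = q.shape[-2], k.shape[-2]
        lead = q.shape[:-2]
        qh = self.q_proj(q).reshape(*lead, Nq, h, dh).transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        kh = self.k_proj(k).reshape(*lead, Nk, h, dh).transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        vh = self.v_proj(v).reshape(*lead, Nk, h, dh).transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)
        logits = (qh @ kh.transpose(*range(len(lead)), len(lead), len(lead) + 2, len(lead) + 1)) * (1.0 / np.sqrt(dh))
        if attn_mask is not None:
            logits = logits + Tensor(attn_mask)
        attn = logits.softmax(axis=-1)
        out = attn @ vh  # (..., h, Nq, dh)
        out = out.transpose(*range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2).reshape(*lead, Nq, h * dh)
        return self.out_proj(out)


class Conv2d(Module):
    """2-D convolution on (C, H, W) arrays via im2col; zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, stride: int = 1, padding: int = 0):
        fan = c_in * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan), size=(c_out, c_in * kernel * kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self._k, self._s, self._p = kernel, stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self._k, self._s, self._p
        C, H, W = x.shape
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        cols = win.transpose(0, 3, 4, 1, 2).reshape(C * k * k, Ho * Wo)
        w, b = self.weight, self.bias
        yflat = w.data @ cols + b.data[:, None]
        out_shape = (w.data.shape[0], Ho, Wo)

        x_, w_, b_ = x, w, b

        def backward(g):
            gf = g.reshape(out_shape[0], Ho * Wo)
            gw = gf @ cols.T
            gb = gf.sum(axis=1)
            gcols = (w_.data.T @ gf).reshape(C, k, k, Ho, Wo)
            gxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    gxp[:, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += gcols[:, ki, kj]
            gx = gxp[:, p:p + H, p:p + W] if p else gxp
            return gx, gw, gb

        return Tensor._make(yflat.reshape(out_shape), (x_, w_, b_), backward)


def _resize_indices(n_in: int, n_out: int):
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0)
    return i0, i1, w1


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (C, H, W) to (C, Ho, Wo); half-pixel-center sampling."""
    C, H, W = x.shape
    Ho, Wo = out_hw
    r0, r1, wr = _resize_indices(H, Ho)
    c0, c1, wc = _resize_indices(W, Wo)
    d = x.data
    top = d[:, r0][:, :, c0] * (1 - wc) + d[:, r0][:, :, c1] * wc
    bot = d[:, r1][:, :, c0] * (1 - wc) + d[:, r1][:, :, c1] * wc
    out = top * (1 - wr)[None, :, None] + bot * wr[None, :, None]

    def backward(g):
        gx = np.zeros_like(d)
        gtop = g * (1 - wr)[None, :, None]
        gbot = g * wr[None, :, None]
        for rows, grow in ((r0, gtop), (r1, gbot)):
            gl = grow * (1 - wc)
            gr = grow * wc
            # scatter over (row, col) pairs
            np.add.at(gx, (slice(None), rows[:, None], c0[None, :]), gl)
            np.add.at(gx, (slice(None), rows[:, None], c1[None, :]), gr)
        return (gx,)

    return Tensor._make(out, (x,), backward)


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    C, H, W = x.shape
    return resize_bilinear(x, (H * scale, W * scale))


def grid_sample_points(values: Tensor, locs: Tensor) -> Tensor:
    """Sample (H, W, D) `values` at float pixel locations (..., 2) as (row, col).

    Bilinear interpolation with zero padding outside; gradients flow to both
    the value grid and the sampling locations (piecewise-linear derivative).
    """
    H, W, D = values.shape
    lead = locs.shape[:-1]
    pts = locs.data.reshape(-1, 2)
    r, c = pts[:, 0], pts[:, 1]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr, fc = r - r0, c - c0

    def gather(ri, ci):
        valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
        out = np.zeros((len(ri), D))
        out[valid] = values.data[ri[valid], ci[valid]]
        return out, valid

    v00, m00 = gather(r0, c0)
    v01, m01 = gather(r0, c0 + 1)
    v10, m10 = gather(r0 + 1, c0)
    v11, m11 = gather(r0 + 1, c0 + 1)
    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc
    out = (v00 * w00[:, None] + v01 * w01[:, None] + v10 * w10[:, None] + v11 * w11[:, None])

    def backward(g):
        g = g.reshape(-1, D)
        gv = np.zeros_like(values.data)
        for (ri, ci, m, w) in ((r0, c0, m00, w00), (r0, c0 + 1, m01, w01),
                               (r0 + 1, c0, m10, w10), (r0 + 1, c0 + 1, m11, w11)):
            np.add.at(gv, (ri[m], ci[m]), g[m] * w[m, None])
        gdot = lambda v: (g * v).sum(axis=1)
        dr = (-(1 - fc) * gdot(v00) - fc * gdot(v01) + (1 - fc) * gdot(v10) + fc * gdot(v11))
        dc = (-(1 - fr) * gdot(v00) + (1 - fr) * gdot(v01) - fr * gdot(v10) + fr * gdot(v11))
        gl = np.stack([dr, dc], axis=-1).reshape(locs.data.shape)
        return gv, gl

    return Tensor._make(out.reshape(*lead, D), (values, locs), backward)


def sinusoidal_embedding_2d(rows: np.ndarray, cols: np.ndarray, dim: int,
                            temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2-D sine/cosine positional embedding for normalized coordinates in [0, 1]."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    d4 = dim // 4
    freq = temperature ** (np.arange(d4) / d4)
    out = np.empty((len(rows), dim))
    for i, coord in enumerate((rows, cols)):
        ang = 2 * np.pi * coord[:, None] / freq[None, :]
        out[:, 2 * i * d4:(2 * i + 1) * d4] = np.sin(ang)
        out[:, (2 * i + 1) * d4:(2 * i + 2) * d4] = np.cos(ang)
    return out


def clip_grad_norm(params, max_norm: float) -> float:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data if self.wd else p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
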