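"""Spatial-transcriptomics preprocessing and consensus ground truth.

Imaging-based spatial transcriptomics (Xenium, MERFISH) provides a DAPI
nuclear stain plus per-molecule transcript coordinates.  For segmentation,
transcripts are rasterized to per-pixel counts and smoothed into a kernel
density map; composite input stacks overlay DAPI, raw transcript signal and
the density map (each min-max scaled).  Ground truth for such data is built
by consensus between two independent segmenters: instances are paired
greedily by descending IoU and, when a pair's IoU exceeds the cutoff (0.3 by
default), the pixelwise intersection becomes a consensus mask.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import MultiplexImage, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["rasterize_transcripts", "density_map", "make_composite",
           "consensus_ground_truth", "validate_transcripts"]


def validate_transcripts(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("x", "y"):
        if col not in table.columns:
            raise ValidationError(f"transcript table missing column {col!r}")
    return table


def rasterize_transcripts(table: pd.DataFrame, height: int, width: int) -> np.ndarray:
    """Per-pixel molecule counts, all genes pooled.

    Out-of-bounds rows are dropped (count logged); the image sum equals the
    number of in-bounds rows.
    """
    validate_transcripts(table)
    img = np.zeros((height, width), dtype=np.float64)
    if len(table) == 0:
        return img
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    ix = np.floor(x).astype(int)
    iy = np.floor(y).astype(int)
    ok = (ix >= 0) & (ix < width) & (iy >= 0) & (iy < height)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("rasterize_transcripts: dropped %d out-of-bounds molecules", dropped)
    np.add.at(img, (iy[ok], ix[ok]), 1.0)
    return img


def density_map(table: pd.DataFrame, height: int, width: int,
                bandwidth: float = 8.0, truncate: float = 5.0) -> np.ndarray:
    """Gaussian kernel density estimate of transcript positions on the pixel grid.

    Each molecule contributes a 2-D Gaussian kernel of scale `bandwidth`
    (pixels) evaluated at pixel centers and normalized so the pixel sum of one
    interior kernel is its molecule count contribution of 1; the map therefore
    integrates to (approximately, up to edge truncation) the molecule count.
    Kernels are truncated at `truncate` standard deviations.
    """
    validate_transcripts(table)
    out = np.zeros((height, width))
    x = table["x"].to_numpy(dtype=float) if len(table) else np.array([])
    y = table["y"].to_numpy(dtype=float) if len(table) else np.array([])
    ok = (x >= 0) & (x < width) & (y >= 0) & (y < height)
    if not ok.any():
        logger.warning("density_map: no in-bounds molecules; returning zero map")
        return out
    r = int(np.ceil(truncate * bandwidth))
    norm = 1.0 / (2.0 * np.pi * bandwidth ** 2)
    for xi, yi in zip(x[ok], y[ok]):
        c0, c1 = max(int(np.floor(xi)) - r, 0), min(int(np.floor(xi)) + r + 1, width)
        r0, r1 = max(int(np.floor(yi)) - r, 0), min(int(np.floor(yi)) + r + 1, height)
        cols = np.arange(c0, c1) + 0.5
        rows = np.arange(r0, r1) + 0.5
        d2 = (rows[:, None] - yi) ** 2 + (cols[None, :] - xi) ** 2
        out[r0:r1, c0:c1] += norm * np.exp(-d2 / (2.0 * bandwidth ** 2))
    return out


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi - lo <= 0:
        logger.warning("make_composite: constant channel scaled to zeros")
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def make_composite(dapi: np.ndarray | None, table: pd.DataFrame | None,
                   bandwidth: float = 8.0, membrane: np.ndarray | None = None,
                   mode: str = "full") -> MultiplexImage:
    """Channel stack for model input: [DAPI, transcript counts, KDE density].

    `mode` selects the subset: "full" (all available), "dapi" (DAPI only,
    mirroring a DAPI-only model), "transcript" (counts + density only,
    mirroring a transcript-only model).  Channels are min-max scaled to
    [0, 1]; composing twice is idempotent.
    """
    if mode not in ("full", "dapi", "transcript"):
        raise ValidationError(f"unknown composite mode {mode!r}")
    channels, names = [], []
    if dapi is not None and mode in ("full", "dapi"):
        channels.append(_minmax(np.asarray(dapi, dtype=float)))
        names.append("dapi")
    if table is not None and mode in ("full", "transcript"):
        ref = dapi if dapi is not None else membrane
        if ref is None:
            raise ValidationError("transcript channels need an image frame (dapi or membrane)")
        H, W = np.asarray(ref).shape
        channels.append(_minmax(rasterize_transcripts(table, H, W)))
        names.append("transcript")
        channels.append(_minmax(density_map(table, H, W, bandwidth)))
        names.append("density")
    if membrane is not None and mode == "full":
        channels.append(_minmax(np.asarray(membrane, dtype=float)))
        names.append("membrane")
    if not channels:
        raise ValidationError("no channels requested")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent channel shapes: {shapes}")
    return MultiplexImage(pixels=np.stack(channels), channel_names=names)


def consensus_ground_truth(masks_a: list[np.ndarray], masks_b: list[np.ndarray],
                           iou_min: float = 0.3) -> list[np.ndarray]:
    """Consensus masks from two segmentations of the same image.

    Instances are paired one-to-one greedily by descending IoU (ties broken by
    smaller index pair); for each pair with IoU > `iou_min` the pixelwise
    intersection is emitted.  Unpaired or low-IoU instances are discarded.
    """
    from .evaluation import mask_iou
    if not masks_a or not masks_b:
        return []
    pairs = []
    for i, ma in enumerate(masks_a):
        for j, mb in enumerate(masks_b):
            if ma.shape != mb.shape:
                raise ValidationError("consensus inputs must share the image frame")
            inter = np.logical_and(ma, mb)
            if inter.any():
                pairs.append((mask_iou(ma, mb), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for iou, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        if iou > iou_min:
            out.append(np.logical_and(masks_a[i], masks_b[j]))
    return out
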