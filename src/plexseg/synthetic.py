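"""Synthetic multiplexed-tissue scenes with exact ground truth.

Emulates the content of multiplexed imaging and imaging-based spatial
transcriptomics data at desk scale: a nuclear channel built from per-cell
Gaussian intensity profiles, a membrane channel tracing each object boundary,
one marker channel per cell class elevated inside cells of that class, large
disc-shaped objects (adipocyte analogues), irregular star-convex polygons
(trabecular-bone analogues), and per-cell transcript point clouds concentrated
around the nucleus.  Every scene is a deterministic function of its seed and
ground-truth masks are pairwise disjoint, so downstream detection, training
and evaluation code can be tested without any external download.

What this generator does NOT emulate: optical point-spread functions, uneven
illumination, autofluorescence, imaging-platform-specific noise statistics,
or 3-D structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import (CocoDataset, InstanceRecord, MultiplexImage, ValidationError,
                   mask_to_box, to_coco)

__all__ = ["ClassProfile", "SceneSpec", "Scene", "generate_scene", "generate_dataset"]


@dataclass
class ClassProfile:
    """Shape and marker statistics of one cell class."""

    name: str = "cell"
    mean_radius: float = 10.0          # px
    ecc_range: tuple[float, float] = (0.0, 0.5)   # axis-ratio deviation range
    marker_intensity: float = 0.8      # mean marker level inside cells of this class

    def __post_init__(self):
        if self.mean_radius <= 0:
            raise ValidationError("mean_radius must be positive")


@dataclass
class SceneSpec:
    """Full description of one synthetic scene; the seed fixes everything."""

    height: int = 128
    width: int = 128
    n_cells: int = 15
    class_profiles: list[ClassProfile] = field(default_factory=lambda: [ClassProfile()])
    class_frequencies: list[float] | None = None   # defaults to uniform
    n_large_objects: int = 0           # adipocyte-like discs, radius >= 3x mean cell radius
    n_irregular: int = 0               # bone-fragment-like jittered star polygons
    transcript_rate: float = 0.0       # mean transcripts per cell (Poisson)
    noise_sd: float = 0.02             # additive Gaussian noise, clipped at 0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_large_objects, self.n_irregular) < 0:
            raise ValidationError("object counts must be nonnegative")
        if not self.class_profiles:
            raise ValidationError("at least one class profile required")
        if self.class_frequencies is not None:
            f = np.asarray(self.class_frequencies, dtype=float)
            if len(f) != len(self.class_profiles) or f.min() < 0 or f.sum() <= 0:
                raise ValidationError("class_frequencies must be nonnegative, one per class")

    @property
    def n_classes(self) -> int:
        return len(self.class_profiles)

    @property
    def channel_names(self) -> list[str]:
        return ["nuclear", "membrane"] + [f"marker_{p.name}" for p in self.class_profiles]


@dataclass
class Scene:
    image: MultiplexImage
    instances: list[InstanceRecord]
    transcripts: pd.DataFrame          # columns: x, y, gene, cell_index
    labels: np.ndarray                 # integer label image (0 = background)


class PackingError(RuntimeError):
    """Requested objects cannot be placed without overlap."""


# ------------------------------------------------------------------ geometry

def _ellipse_mask(H, W, cy, cx, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[0:H, 0:W]
    dy, dx = rr - cy, cc - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return u * u + v * v <= 1.0


def _star_polygon_mask(H, W, cy, cx, radius, rng, n_vertices=9, jitter=0.55) -> np.ndarray:
    """Irregular star-convex polygon: radial jitter on evenly spaced vertices."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * (1.0 + jitter * rng.uniform(-1, 1, n_vertices))
    radii = np.clip(radii, radius * 0.25, None)
    ys = cy + radii * np.sin(angles)
    xs = cx + radii * np.cos(angles)
    from skimage.draw import polygon
    rr, cc = polygon(ys, xs, shape=(H, W))
    mask = np.zeros((H, W), dtype=bool)
    mask[rr, cc] = True
    return mask


def _place(occupied: np.ndarray, make_mask, rng, margin: float, max_tries: int = 200):
    """Rejection-sample a non-overlapping placement; fall back to the free
    position nearest the last rejected proposal; raise PackingError if none."""
    H, W = occupied.shape
    last = None
    for _ in range(max_tries):
        cy = rng.uniform(margin, H - margin)
        cx = rng.uniform(margin, W - margin)
        mask = make_mask(cy, cx)
        if mask.any() and not (mask & occupied).any():
            return mask
        last = (cy, cx)
    # nearest-free fallback: centers whose clearance exceeds the object margin
    clearance = ndimage.distance_transform_edt(~occupied)
    ok = clearance >= margin
    ok[:int(margin), :] = ok[-max(int(margin), 1):, :] = False
    ok[:, :int(margin)] = ok[:, -max(int(margin), 1):] = False
    cand = np.argwhere(ok)
    if len(cand):
        ref = np.array(last if last is not None else (H / 2, W / 2))
        order = np.argsort(((cand - ref) ** 2).sum(axis=1))
        for idx in order[:200]:
            cy, cx = cand[idx]
            mask = make_mask(float(cy), float(cx))
            if mask.any() and not (mask & occupied).any():
                return mask
    raise PackingError("could not place object without overlap; scene too crowded")


# ----------------------------------------------------------------- generator

def generate_scene(spec: SceneSpec) -> Scene:
    """Render one scene: image channels, disjoint instance masks, transcripts."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    K = spec.n_classes
    mean_r = float(np.mean([p.mean_radius for p in spec.class_profiles]))

    occupied = np.zeros((H, W), dtype=bool)
    masks: list[np.ndarray] = []
    classes: list[int] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    kinds: list[str] = []

    freqs = (np.asarray(spec.class_frequencies, dtype=float)
             if spec.class_frequencies is not None else np.ones(K))
    freqs = freqs / freqs.sum()

    # large discs first (they need the most room), then irregular, then cells
    for _ in range(spec.n_large_objects):
        r = 3.0 * mean_r * rng.uniform(1.0, 1.3)
        mask = _place(occupied, lambda cy, cx, r=r: _ellipse_mask(H, W, cy, cx, r, r, 0.0),
                      rng, margin=r)
        occupied |= mask
        masks.append(mask); classes.append(int(rng.choice(K, p=freqs)))
        cy, cx = ndimage.center_of_mass(mask)
        centers.append((cy, cx)); radii.append(r); kinds.append("large")

    for _ in range(spec.n_irregular):
        r = 2.0 * mean_r * rng.uniform(0.8, 1.4)
        mask = _place(occupied,
                      lambda cy, cx, r=r: _star_polygon_mask(H, W, cy, cx, r, rng),
                      rng, margin=r)
        occupied |= mask
        masks.append(mask); classes.append(int(rng.choice(K, p=freqs)))
        cy, cx = ndimage.center_of_mass(mask)
        centers.append((cy, cx)); radii.append(r); kinds.append("irregular")

    for _ in range(spec.n_cells):
        cls = int(rng.choice(K, p=freqs))
        prof = spec.class_profiles[cls]
        r = max(2.0, prof.mean_radius * rng.uniform(0.8, 1.2))
        ecc = rng.uniform(*prof.ecc_range)
        a = r * (1.0 + ecc)
        b = r * r / a  # preserve pi * r^2 area
        theta = rng.uniform(0, np.pi)
        mask = _place(occupied,
                      lambda cy, cx: _ellipse_mask(H, W, cy, cx, a, b, theta),
                      rng, margin=a + 1)
        occupied |= mask
        masks.append(mask); classes.append(cls)
        cy, cx = ndimage.center_of_mass(mask)
        centers.append((cy, cx)); radii.append(r); kinds.append("cell")

    # --- channels -----------------------------------------------------------
    pixels = np.zeros((2 + K, H, W))
    rr, cc = np.mgrid[0:H, 0:W]
    for mask, (cy, cx), r, kind in zip(masks, centers, radii, kinds):
        if kind == "cell":
            sigma = max(r / 2.0, 1.0)
            prof = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma ** 2))
            pixels[0] += prof * mask
        ring = mask & ~ndimage.binary_erosion(mask, iterations=2)
        pixels[1][ring] = 1.0
    for mask, cls in zip(masks, classes):
        level = spec.class_profiles[cls].marker_intensity
        pixels[2 + cls][mask] = level

    pixels = np.clip(pixels, 0.0, 1.0)
    if spec.noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, spec.noise_sd, pixels.shape), 0.0, None)

    # --- transcripts --------------------------------------------------------
    rows = []
    if spec.transcript_rate > 0:
        for i, (mask, cls, (cy, cx), r, kind) in enumerate(
                zip(masks, classes, centers, radii, kinds)):
            if kind != "cell":
                continue
            n = rng.poisson(spec.transcript_rate)
            fg = np.argwhere(mask)
            for _ in range(n):
                for _try in range(50):
                    y = rng.normal(cy, r / 2.0)
                    x = rng.normal(cx, r / 2.0)
                    iy, ix = int(np.floor(y)), int(np.floor(x))
                    if 0 <= iy < H and 0 <= ix < W and mask[iy, ix]:
                        break
                else:  # fall back to a uniform point inside a random mask pixel
                    iy, ix = fg[rng.integers(len(fg))]
                    y = iy + rng.uniform(0, 0.999)
                    x = ix + rng.uniform(0, 0.999)
                # marker gene of own class most of the time, background gene otherwise
                if rng.uniform() < 0.8:
                    gene = f"gene_{spec.class_profiles[cls].name}"
                else:
                    gene = f"bg_{rng.integers(5)}"
                rows.append((x, y, gene, i))
    transcripts = pd.DataFrame(rows, columns=["x", "y", "gene", "cell_index"])

    instances = [InstanceRecord(mask=m, box=mask_to_box(m), class_id=c, score=1.0)
                 for m, c in zip(masks, classes)]
    labels = np.zeros((H, W), dtype=np.int64)
    for i, m in enumerate(masks, start=1):
        labels[m] = i
    image = MultiplexImage(pixels=pixels, channel_names=spec.channel_names)
    return Scene(image=image, instances=instances, transcripts=transcripts, labels=labels)


def generate_dataset(spec: SceneSpec, n_images: int, seed: int):
    """Generate `n_images` scenes with per-image derived seeds.

    Returns (CocoDataset, list of Scene).  Image file names are synthetic
    (`scene_###.tif`); pixel data lives in the returned scenes.
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_images)
    scenes = []
    entries = []
    for i, child in enumerate(children):
        sub = SceneSpec(**{**vars(spec), "seed": int(child.generate_state(1)[0] % (2 ** 31))})
        scene = generate_scene(sub)
        scenes.append(scene)
        entries.append((f"scene_{i:03d}.tif", spec.height, spec.width, scene.instances))
    names = [p.name for p in spec.class_profiles]
    return to_coco(entries, names), scenes
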