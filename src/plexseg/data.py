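"""Domain types and I/O: multichannel images, instance masks, COCO interchange.

Conventions used throughout the package:

* Pixel grids are row-major with the origin at the top-left corner, and a
  pixel at row r / column c occupies the half-open square [r, r+1) x [c, c+1).
  The tight box of a single-pixel mask therefore has width and height exactly 1.
* Boxes are stored center-based as (cx, cy, w, h), in pixel units at the I/O
  boundary and normalized to [0, 1] inside the detector.
* COCO JSON files use the standard top-left (x, y, w, h) box convention and
  uncompressed column-major run-length encoded masks, so they are lossless
  round trips of the in-memory representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# --------------------------------------------------------------------- types

@dataclass
class MultiplexImage:
    """A C x H x W stack of named intensity channels."""

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be C x H x W")
        c, h, w = self.pixels.shape
        if c < 1 or h < 8 or w < 8:
            raise ValidationError(f"image too small: C={c}, H={h}, W={w} (need C>=1, H,W>=8)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image intensities must be finite")
        if len(self.channel_names) != c:
            raise ValidationError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != c:
            raise ValidationError("channel_names must be unique")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]


@dataclass
class BBox:
    """Center-based box (cx, cy, w, h), pixel or normalized frame."""

    x: float
    y: float
    w: float
    h: float
    frame: str = "pixel"  # "pixel" | "normalized"

    def __post_init__(self):
        if self.frame not in ("pixel", "normalized"):
            raise ValidationError(f"unknown box frame {self.frame!r}")
        if not (self.w > 0 and self.h > 0):
            raise ValidationError("box width and height must be positive")
        if self.frame == "normalized":
            for v in (self.x, self.y, self.w, self.h):
                if not (0.0 <= v <= 1.0):
                    raise ValidationError("normalized box values must lie in [0, 1]")

    def to_normalized(self, height: int, width: int) -> "BBox":
        if self.frame == "normalized":
            return self
        return BBox(self.x / width, self.y / height, self.w / width, self.h / height,
                    frame="normalized")

    def to_pixel(self, height: int, width: int) -> "BBox":
        if self.frame == "pixel":
            return self
        return BBox(self.x * width, self.y * height, self.w * width, self.h * height,
                    frame="pixel")

    def to_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x - self.w / 2, self.y - self.h / 2,
                self.x + self.w / 2, self.y + self.h / 2)

    @staticmethod
    def from_xyxy(x0: float, y0: float, x1: float, y1: float, frame: str = "pixel") -> "BBox":
        return BBox((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0, frame=frame)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=np.float64)


@dataclass
class InstanceRecord:
    """One segmented object: binary mask, tight box, class id, confidence."""

    mask: np.ndarray
    box: BBox
    class_id: int
    score: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not self.mask.any():
            raise ValidationError("instance mask has no foreground pixels")
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError("score must lie in [0, 1]")

    @staticmethod
    def from_mask(mask: np.ndarray, class_id: int = 0, score: float = 1.0) -> "InstanceRecord":
        return InstanceRecord(mask=mask, box=mask_to_box(mask), class_id=class_id, score=score)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class CocoDataset:
    """COCO-style instance dictionary (images / annotations / categories)."""

    images: list[dict] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)
    categories: list[dict] = field(default_factory=list)

    def validate(self):
        image_ids = {im["id"] for im in self.images}
        cat_ids = {c["id"] for c in self.categories}
        if len(image_ids) != len(self.images):
            raise ValidationError("duplicate image ids")
        for ann in self.annotations:
            if ann["image_id"] not in image_ids:
                raise ValidationError(f"annotation references unknown image id {ann['image_id']}")
            if ann["category_id"] not in cat_ids:
                raise ValidationError(f"annotation references unknown category id {ann['category_id']}")
        return self

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"images": self.images, "annotations": self.annotations,
             "categories": self.categories}))

    @staticmethod
    def from_json(path) -> "CocoDataset":
        d = json.loads(Path(path).read_text())
        return CocoDataset(d["images"], d["annotations"], d["categories"]).validate()


# ----------------------------------------------------------------------- RLE

def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO run-length encoding (column-major, runs start with 0s)."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    flat = mask.flatten(order="F").astype(np.int8)
    # run boundaries
    diffs = np.flatnonzero(np.diff(flat))
    starts = np.concatenate([[0], diffs + 1])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    counts = lengths.tolist()
    if flat[0] == 1:  # COCO counts always begin with a (possibly zero) run of 0s
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------- operations

def read_image(path) -> MultiplexImage:
    """Read a (multi-page or channel-axis) TIFF as a MultiplexImage.

    Intensities are cast to floating point without rescaling; channel order is
    preserved.  For a 3-D array the smaller of the first/last axes is taken as
    the channel axis (multi-page TIFFs put channels first).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        if arr.shape[0] > arr.shape[2]:
            arr = arr.transpose(2, 0, 1)
    else:
        raise ValidationError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    names = [f"ch{i}" for i in range(arr.shape[0])]
    return MultiplexImage(pixels=arr.astype(np.float64), channel_names=names)


def write_image(path, image: MultiplexImage):
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_labels(path) -> np.ndarray:
    """Read an integer label image (0 = background)."""
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise ValidationError("label image must be 2-D")
    return arr.astype(np.int64)


def write_labels(path, labels: np.ndarray):
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max(initial=0) < 2 ** 16 else np.uint32
    tifffile.imwrite(str(path), labels.astype(dtype))


def mask_to_box(mask: np.ndarray) -> BBox:
    """Tight axis-aligned pixel-frame box around the mask foreground.

    Under the half-open pixel convention a foreground column span [c0, c1]
    covers [c0, c1 + 1), giving width c1 - c0 + 1.
    """
    mask = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValidationError("cannot derive a box from an empty mask")
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    w = c1 - c0 + 1
    h = r1 - r0 + 1
    return BBox(x=c0 + w / 2, y=r0 + h / 2, w=float(w), h=float(h), frame="pixel")


def labeled_mask_to_instances(labels: np.ndarray, class_map: dict[int, int] | None = None,
                              score: float = 1.0) -> list[InstanceRecord]:
    """Split an integer label image into one InstanceRecord per nonzero label.

    Score defaults to 1 following the convention that methods without a
    confidence output are assigned full confidence.
    """
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0:
        raise ValidationError("labels must be nonnegative")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if class_map is not None:
        missing = [int(i) for i in ids if int(i) not in class_map]
        if missing:
            raise ValidationError(f"labels missing from class_map: {missing}")
    out = []
    for lab in ids:
        cls = class_map[int(lab)] if class_map is not None else 0
        out.append(InstanceRecord.from_mask(labels == lab, class_id=cls, score=score))
    return out


def instances_to_labels(instances: list[InstanceRecord], height: int, width: int) -> np.ndarray:
    """Paint instances into a label image (1-based, later instances win ties)."""
    labels = np.zeros((height, width), dtype=np.int64)
    for i, inst in enumerate(instances, start=1):
        labels[inst.mask] = i
    return labels


@dataclass
class ImagePatch:
    image: MultiplexImage
    instances: list[InstanceRecord]
    origin: tuple[int, int]  # (row, col) of the patch's top-left pixel


def patchify(image: MultiplexImage, instances: list[InstanceRecord], patch: int,
             pad_edges: bool = False) -> list[ImagePatch]:
    """Tile an image into non-overlapping `patch` x `patch` windows.

    Incomplete edge tiles are dropped unless `pad_edges`, which reflect-pads
    the image (masks are zero-padded).  Instances are cropped per patch;
    instances whose cropped mask is empty are dropped, and boxes are re-derived
    from the cropped masks, so an instance straddling a border appears in each
    patch with the areas summing to the original.
    """
    H, W = image.height, image.width
    if patch > min(H, W):
        raise ValidationError(f"patch size {patch} exceeds image extent {H}x{W}")
    pixels = image.pixels
    masks = [inst.mask for inst in instances]
    if pad_edges:
        Hp = int(np.ceil(H / patch)) * patch
        Wp = int(np.ceil(W / patch)) * patch
        pixels = np.pad(pixels, ((0, 0), (0, Hp - H), (0, Wp - W)), mode="reflect")
        masks = [np.pad(m, ((0, Hp - H), (0, Wp - W))) for m in masks]
        H, W = Hp, Wp
    out = []
    for r0 in range(0, H - patch + 1, patch):
        for c0 in range(0, W - patch + 1, patch):
            sub = MultiplexImage(pixels[:, r0:r0 + patch, c0:c0 + patch].copy(),
                                 list(image.channel_names), image.pixel_size_um)
            sub_inst = []
            for inst, m in zip(instances, masks):
                crop = m[r0:r0 + patch, c0:c0 + patch]
                if crop.any():
                    sub_inst.append(InstanceRecord.from_mask(crop, inst.class_id, inst.score))
            out.append(ImagePatch(sub, sub_inst, (r0, c0)))
    return out


def to_coco(entries: list[tuple[str, int, int, list[InstanceRecord]]],
            category_names: list[str]) -> CocoDataset:
    """Build a COCO dataset from (file_name, height, width, instances) entries."""
    categories = [{"id": k, "name": name} for k, name in enumerate(category_names)]
    images, annotations = [], []
    ann_id = 1
    for img_id, (fname, h, w, instances) in enumerate(entries, start=1):
        images.append({"id": img_id, "file_name": fname, "height": h, "width": w})
        for inst in instances:
            if inst.mask.shape != (h, w):
                raise ValidationError(
                    f"instance mask shape {inst.mask.shape} inconsistent with image {h}x{w}")
            x0, y0, x1, y1 = inst.box.to_xyxy()
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": int(inst.class_id),
                "segmentation": rle_encode(inst.mask),
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": inst.area, "iscrowd": 0, "score": float(inst.score),
            })
            ann_id += 1
    return CocoDataset(images, annotations, categories).validate()


def from_coco(ds: CocoDataset) -> tuple[list[tuple[str, int, int, list[InstanceRecord]]], list[str]]:
    """Inverse of :func:`to_coco`; lossless for masks, boxes and class ids."""
    ds.validate()
    by_image: dict[int, list[InstanceRecord]] = {im["id"]: [] for im in ds.images}
    for ann in ds.annotations:
        mask = rle_decode(ann["segmentation"])
        by_image[ann["image_id"]].append(
            InstanceRecord.from_mask(mask, ann["category_id"], ann.get("score", 1.0)))
    entries = [(im["file_name"], im["height"], im["width"], by_image[im["id"]])
               for im in ds.images]
    names = [c["name"] for c in sorted(ds.categories, key=lambda c: c["id"])]
    return entries, names


def split_dataset(ds: CocoDataset, fractions: tuple[float, float, float],
                  seed: int) -> tuple[CocoDataset, CocoDataset, CocoDataset]:
    """Image-level train/val/test split, deterministic given the seed."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValidationError("split fractions must sum to 1")
    n = len(ds.images)
    if n < 3:
        raise ValidationError("need at least 3 images to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train - 1) if n_train + n_val >= n else n_val
    idx_train = set(order[:n_train].tolist())
    idx_val = set(order[n_train:n_train + n_val].tolist())

    def subset(keep_idx) -> CocoDataset:
        keep_ids = {ds.images[i]["id"] for i in keep_idx}
        return CocoDataset(
            images=[im for i, im in enumerate(ds.images) if i in keep_idx],
            annotations=[a for a in ds.annotations if a["image_id"] in keep_ids],
            categories=list(ds.categories))

    all_idx = set(range(n))
    return (subset(idx_train), subset(idx_val), subset(all_idx - idx_train - idx_val))
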