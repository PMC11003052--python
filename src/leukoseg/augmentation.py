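"""Seedable photometric and geometric augmentation of leukocyte crops.

Five operations: horizontal/vertical flip, brightness shift, contrast
scaling about mid-gray, rotation, and shear.  Geometric warps use
nearest-neighbor sampling about the image center so outputs remain exact
uint8 images of the same shape; pixels pulled from outside the frame are
filled with the background gray used throughout the pipeline.

``augment_dataset`` expands a labeled dataset by a fixed number of variants
per image, each variant drawn from an independently seeded stream so the
augmented set is a pure function of ``(dataset, config)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .imageio_core import LabeledDataset, Record, as_rgb_image
from .segmentation import PAD_GRAY

__all__ = [
    "AugmentationConfig",
    "flip",
    "adjust_brightness",
    "adjust_contrast",
    "rotate",
    "shear",
    "augment_dataset",
]


@dataclass
class AugmentationConfig:
    """Sampling ranges for the augmentation draws.

    Defaults are mild enough to keep the leukocyte inside the frame:
    brightness within +/-40 intensity units, contrast in [0.7, 1.3],
    rotation within +/-20 degrees, shear within +/-0.2, and each enabled
    flip applied with probability 0.5.
    """

    brightness_range: tuple[float, float] = (-40.0, 40.0)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    rotation_range: tuple[float, float] = (-20.0, 20.0)
    shear_range: tuple[float, float] = (-0.2, 0.2)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    seed: int = 0
    per_image_count: int = 2

    def __post_init__(self):
        for name in ("brightness_range", "contrast_range", "rotation_range", "shear_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        if self.contrast_range[0] <= 0:
            raise ValueError(f"contrast factors must be > 0, got {self.contrast_range}")
        if self.per_image_count < 0:
            raise ValueError("per_image_count must be >= 0")


def flip(img: np.ndarray, axis: Literal["horizontal", "vertical"]) -> np.ndarray:
    """Mirror the image: 'horizontal' swaps left/right, 'vertical' top/bottom."""
    img = as_rgb_image(img)
    if axis == "horizontal":
        return img[:, ::-1].copy()
    if axis == "vertical":
        return img[::-1].copy()
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def adjust_brightness(img: np.ndarray, delta: float) -> np.ndarray:
    """Add ``delta`` to every channel, clipping to [0, 255]."""
    img = as_rgb_image(img)
    out = np.clip(img.astype(np.float64) + delta, 0, 255)
    return np.floor(out + 0.5).astype(np.uint8)


def adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale the deviation from mid-gray 127.5 by ``factor``, clipping to [0, 255]."""
    if factor < 0:
        raise ValueError(f"contrast factor must be >= 0, got {factor}")
    img = as_rgb_image(img)
    out = np.clip(127.5 + factor * (img.astype(np.float64) - 127.5), 0, 255)
    return np.floor(out + 0.5).astype(np.uint8)


def _warp_nearest(img: np.ndarray, inv: np.ndarray, fill: int) -> np.ndarray:
    """Apply an inverse-mapping 2x2 affine about the image center, NN sampling."""
    h, w = img.shape[:2]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr, dc = rows - cr, cols - cc
    src_r = np.floor(inv[0, 0] * dr + inv[0, 1] * dc + cr + 0.5).astype(np.int64)
    src_c = np.floor(inv[1, 0] * dr + inv[1, 1] * dc + cc + 0.5).astype(np.int64)
    inside = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    out = np.full_like(img, fill)
    out[inside] = img[src_r[inside], src_c[inside]]
    return out


def rotate(img: np.ndarray, angle_deg: float, fill: int = PAD_GRAY) -> np.ndarray:
    """Rotate counterclockwise about the image center; shape unchanged.

    Nearest-neighbor sampling; a 90-degree rotation of an even-sized image is
    an exact quarter-turn pixel permutation.
    """
    img = as_rgb_image(img)
    if angle_deg % 360 == 0:
        return img.copy()
    th = math.radians(angle_deg)
    # inverse map in (row, col) coordinates for a CCW rotation
    inv = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    return _warp_nearest(img, inv, fill)


def shear(img: np.ndarray, factor: float, fill: int = PAD_GRAY) -> np.ndarray:
    """Horizontal shear about the center: column offset proportional to row."""
    img = as_rgb_image(img)
    if factor == 0:
        return img.copy()
    # forward map c' = c + factor * (r - cr); invert exactly
    inv = np.array([[1.0, 0.0], [-factor, 1.0]])
    return _warp_nearest(img, inv, fill)


def _augment_once(img: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    """One variant: flips, rotation, shear, then contrast and brightness."""
    out = img
    if cfg.flip_horizontal and rng.random() < 0.5:
        out = flip(out, "horizontal")
    if cfg.flip_vertical and rng.random() < 0.5:
        out = flip(out, "vertical")
    angle = rng.uniform(*cfg.rotation_range)
    if angle != 0:
        out = rotate(out, angle)
    s = rng.uniform(*cfg.shear_range)
    if s != 0:
        out = shear(out, s)
    out = adjust_contrast(out, rng.uniform(*cfg.contrast_range))
    delta = rng.uniform(*cfg.brightness_range)
    return adjust_brightness(out, delta)


def augment_dataset(dataset: LabeledDataset, cfg: AugmentationConfig) -> LabeledDataset:
    """Expand every record with ``per_image_count`` seeded variants.

    Output order is original followed by its variants, per record; labels are
    preserved and the result has ``n * (1 + per_image_count)`` records.
    """
    if cfg.per_image_count == 0:
        return LabeledDataset(list(dataset.records))
    children = np.random.SeedSequence(cfg.seed).spawn(len(dataset))
    records: list[Record] = []
    for rec, child in zip(dataset.records, children):
        records.append(rec)
        rng = np.random.default_rng(child)
        for k in range(cfg.per_image_count):
            records.append(
                Record(_augment_once(rec.image, cfg, rng), rec.label, f"{rec.name}#aug{k}")
            )
    return LabeledDataset(records)
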