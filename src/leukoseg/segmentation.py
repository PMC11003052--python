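"""Rule-based leukocyte isolation from stained blood-smear images.

A stained smear image has three regions: a gray background, light-brown
erythrocytes, and one blue/purple leukocyte.  Segmentation proceeds by color
rules on the raw RGB channels:

* **background**: every channel strictly above ``threshold_1`` (default 182),
* **erythrocyte**: blue strictly below ``threshold_2`` (default 150), or
  red strictly above blue,
* **leukocyte**: neither of the above.

The leukocyte mask is cleaned by morphological opening (erosion then dilation
with a disk), the largest 8-connected component is boxed, and a fixed-size
window centered on that box is cropped from the image.

Both thresholds can also be recomputed per image with Otsu's method
(between-class-variance maximization): ``threshold_1`` from the luminance
histogram and ``threshold_2`` from the blue-channel histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .imageio_core import as_rgb_image

__all__ = [
    "ThresholdConfig",
    "StructuringElement",
    "BoundingBox",
    "otsu_threshold",
    "luminance_histogram",
    "channel_histogram",
    "background_mask",
    "erythrocyte_mask",
    "leukocyte_mask",
    "region_partition",
    "dilate",
    "erode",
    "open_mask",
    "largest_component_bbox",
    "crop_leukocyte",
    "segment_pipeline",
]

#: Gray fill used when a crop window extends past the image: a background-like
#: value that satisfies the background rule at the default threshold, so
#: padding never creates spurious leukocyte pixels.
PAD_GRAY = 200

#: Dataset-level defaults for the two color thresholds.
DEFAULT_THRESHOLD_1 = 182
DEFAULT_THRESHOLD_2 = 150

DEFAULT_CROP_SIZE = 128
DEFAULT_SE_RADIUS = 5


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class ThresholdConfig:
    """Thresholds for the background and erythrocyte color rules.

    ``mode="fixed"`` uses the stored values; ``mode="otsu"`` recomputes both
    per image (luminance histogram for ``threshold_1``, blue-channel histogram
    for ``threshold_2``).
    """

    threshold_1: int = DEFAULT_THRESHOLD_1
    threshold_2: int = DEFAULT_THRESHOLD_2
    mode: Literal["fixed", "otsu"] = "fixed"

    def __post_init__(self):
        for name in ("threshold_1", "threshold_2"):
            v = getattr(self, name)
            if not 0 <= int(v) <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.mode not in ("fixed", "otsu"):
            raise ValueError(f"mode must be 'fixed' or 'otsu', got {self.mode!r}")

    def resolve(self, img: np.ndarray) -> tuple[int, int]:
        """Return ``(threshold_1, threshold_2)`` for ``img`` under this mode."""
        if self.mode == "fixed":
            return int(self.threshold_1), int(self.threshold_2)
        t1 = otsu_threshold(luminance_histogram(img))
        t2 = otsu_threshold(channel_histogram(img, 2))
        return t1, t2


@dataclass(frozen=True)
class StructuringElement:
    """Boolean footprint with an origin, for the morphological operations."""

    footprint: np.ndarray
    origin: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be a non-empty 2-D boolean grid")
        origin = self.origin
        if origin is None:
            origin = (fp.shape[0] // 2, fp.shape[1] // 2)
        origin = (int(origin[0]), int(origin[1]))
        if not (0 <= origin[0] < fp.shape[0] and 0 <= origin[1] < fp.shape[1]):
            raise ValueError(f"origin {origin} outside footprint of shape {fp.shape}")
        if not fp[origin]:
            raise ValueError(f"footprint must be true at the origin {origin}")
        object.__setattr__(self, "footprint", fp)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        """Disk footprint: all offsets within Euclidean distance ``radius``."""
        r = int(radius)
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        return cls(yy * yy + xx * xx <= r * r, (r, r))

    @classmethod
    def square(cls, side: int) -> "StructuringElement":
        return cls(np.ones((side, side), dtype=bool))

    def offsets(self) -> np.ndarray:
        """True positions relative to the origin, shape (k, 2)."""
        rows, cols = np.nonzero(self.footprint)
        return np.stack([rows - self.origin[0], cols - self.origin[1]], axis=1)

    def reflected(self) -> "StructuringElement":
        """Point reflection about the origin."""
        fp = self.footprint[::-1, ::-1]
        h, w = fp.shape
        return StructuringElement(fp, (h - 1 - self.origin[0], w - 1 - self.origin[1]))


@dataclass(frozen=True)
class BoundingBox:
    """Half-open, 0-based box: rows ``[row_min, row_max)``, cols ``[col_min, col_max)``."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate bounding box {self}")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError(f"negative bounding box corner {self}")

    @property
    def center(self) -> tuple[int, int]:
        return ((self.row_min + self.row_max) // 2, (self.col_min + self.col_max) // 2)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def luminance_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of rounded Rec.601 luminance 0.299R+0.587G+0.114B."""
    img = as_rgb_image(img)
    lum = np.rint(
        0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2]
    ).astype(np.int64)
    return np.bincount(lum.ravel(), minlength=256)[:256]


def channel_histogram(img: np.ndarray, channel: int) -> np.ndarray:
    """256-bin histogram of one channel."""
    img = as_rgb_image(img)
    return np.bincount(img[:, :, channel].ravel(), minlength=256)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold maximizing between-class variance of a 256-bin histogram.

    A candidate ``t`` splits intensities into ``<= t`` and ``> t``; the
    between-class variance ``w0*w1*(mu0-mu1)^2`` is evaluated for every
    ``t`` in 0..255 and the smallest maximizer is returned (plateaus are
    resolved deterministically toward the low end).  A histogram concentrated
    on a single intensity returns that intensity with a warning.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"histogram must have 256 bins, got shape {hist.shape}")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("cannot threshold an all-zero histogram")
    nonzero = np.flatnonzero(hist)
    if len(nonzero) == 1:
        v = int(nonzero[0])
        warnings.warn(f"degenerate histogram: single intensity {v}; returning it")
        return v
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / total                      # mass of class {<= t}
    mu_cum = np.cumsum(hist * levels) / total
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, 0.0)
    return int(np.argmax(sigma_b))                    # argmax returns first max


# ---------------------------------------------------------------------------
# Color-rule masks
# ---------------------------------------------------------------------------

def background_mask(img: np.ndarray, threshold_1: int = DEFAULT_THRESHOLD_1) -> np.ndarray:
    """True where red, green and blue are all strictly above ``threshold_1``."""
    img = as_rgb_image(img)
    r, g, b = img[:, :, 0], img[:, :, 1], img[:, :, 2]
    return (r > threshold_1) & (g > threshold_1) & (b > threshold_1)


def erythrocyte_mask(img: np.ndarray, threshold_2: int = DEFAULT_THRESHOLD_2) -> np.ndarray:
    """True where blue is strictly below ``threshold_2`` or red exceeds blue."""
    img = as_rgb_image(img)
    r, b = img[:, :, 0].astype(np.int16), img[:, :, 2].astype(np.int16)
    return (b < threshold_2) | (r > b)


def leukocyte_mask(img: np.ndarray, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """True where a pixel is neither background nor erythrocyte."""
    cfg = cfg or ThresholdConfig()
    t1, t2 = cfg.resolve(img)
    return ~background_mask(img, t1) & ~erythrocyte_mask(img, t2)


def region_partition(img: np.ndarray, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Single-label map with precedence background > erythrocyte > leukocyte.

    The raw background and erythrocyte rules can both hold at one pixel (a
    bright pixel with red above blue); this helper assigns each pixel exactly
    one region for display and bookkeeping: 0 background, 1 erythrocyte,
    2 leukocyte.
    """
    cfg = cfg or ThresholdConfig()
    t1, t2 = cfg.resolve(img)
    bg = background_mask(img, t1)
    ery = erythrocyte_mask(img, t2) & ~bg
    out = np.full(bg.shape, 2, dtype=np.uint8)
    out[ery] = 1
    out[bg] = 0
    return out


# ---------------------------------------------------------------------------
# Binary morphology
# ---------------------------------------------------------------------------

def _shift(mask: np.ndarray, dr: int, dc: int, fill: bool) -> np.ndarray:
    """Translate ``mask`` by (dr, dc), filling vacated pixels with ``fill``."""
    h, w = mask.shape
    out = np.full((h, w), fill, dtype=bool)
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    if rs_src.start < rs_src.stop and cs_src.start < cs_src.stop:
        out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation: true where the reflected element, placed there, overlaps the mask.

    Pixels beyond the image border count as false.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for dr, dc in se.offsets():
        out |= _shift(mask, int(dr), int(dc), fill=False)
    return out


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion: true where the element, placed there, fits entirely in the mask.

    Out-of-border positions count as false, so erosion shrinks at the border.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.ones_like(mask)
    for dr, dc in se.offsets():
        out &= _shift(mask, -int(dr), -int(dc), fill=False)
    return out


def open_mask(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological opening: erosion followed by dilation with the same element."""
    return dilate(erode(mask, se), se)


# ---------------------------------------------------------------------------
# Component selection and cropping
# ---------------------------------------------------------------------------

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def largest_component_bbox(mask: np.ndarray) -> BoundingBox:
    """Tight box of the largest 8-connected component of ``mask``.

    Ties on pixel count are broken toward the component whose box corner
    ``(row_min, col_min)`` is smallest in row-major order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no leukocyte found: mask has no foreground pixels")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    sizes = np.bincount(labels.ravel())[1:]           # skip background label 0
    slices = ndimage.find_objects(labels)
    best = None
    for lab in range(n):
        if sizes[lab] != sizes.max():
            continue
        sl = slices[lab]
        key = (sl[0].start, sl[1].start)
        if best is None or key < best[0]:
            best = (key, sl)
    sl = best[1]
    return BoundingBox(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)


def crop_leukocyte(
    img: np.ndarray, bbox: BoundingBox, size: int = DEFAULT_CROP_SIZE
) -> np.ndarray:
    """Extract a ``size`` x ``size`` window centered on the box center.

    The window is clamped to stay inside the image; a dimension smaller than
    ``size`` is padded symmetrically with the background gray ``PAD_GRAY``.
    """
    img = as_rgb_image(img)
    h, w = img.shape[:2]
    cr, cc = bbox.center

    def axis_window(c: int, extent: int) -> tuple[int, int, int, int]:
        # start in source coords, length copied, pad before, pad after
        if extent >= size:
            start = min(max(c - size // 2, 0), extent - size)
            return start, size, 0, 0
        pad = size - extent
        return 0, extent, pad // 2, pad - pad // 2

    r0, rl, rpb, rpa = axis_window(cr, h)
    c0, cl, cpb, cpa = axis_window(cc, w)
    out = np.full((size, size, 3), PAD_GRAY, dtype=np.uint8)
    out[rpb:rpb + rl, cpb:cpb + cl] = img[r0:r0 + rl, c0:c0 + cl]
    return out


def segment_pipeline(
    img: np.ndarray,
    cfg: ThresholdConfig | None = None,
    se: StructuringElement | None = None,
    crop_size: int = DEFAULT_CROP_SIZE,
) -> tuple[np.ndarray, BoundingBox, np.ndarray]:
    """Full isolation chain: color masks -> opening -> largest box -> crop.

    Returns ``(crop, bbox, opened_leukocyte_mask)``.  Raises the
    "no leukocyte found" error when the opened mask is empty (e.g. an
    all-background image).
    """
    cfg = cfg or ThresholdConfig()
    se = se or StructuringElement.disk(DEFAULT_SE_RADIUS)
    mask = leukocyte_mask(img, cfg)
    opened = open_mask(mask, se)
    bbox = largest_component_bbox(opened)
    crop = crop_leukocyte(img, bbox, size=crop_size)
    return crop, bbox, opened
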