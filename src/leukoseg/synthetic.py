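"""Synthetic blood-smear scenes with ground truth.

Each scene emulates the three-region structure of a stained smear: a gray
background, light-brown erythrocyte ellipses, and exactly one blue/purple
leukocyte blob.  Colors are sampled strictly inside the decision regions of
the segmentation color rules with >= 5 intensity units of margin, so region
membership is unambiguous by construction:

* background: all channels in [190, 230] (every channel > 182),
* erythrocyte: r in [180, 220], g in [120, 160], b in [110, 145]
  (blue < 150 and red > blue; green <= 160 < 182 keeps it out of the
  background rule),
* leukocyte: r in [100, 140], g in [60, 110], b in [160, 210]
  (red < 182 and blue >= 160 with red < blue fails both other rules).

The four classes differ by nucleus morphology inside the blob: neutrophils
carry 3-5 small dark lobes, eosinophils two lobes plus a bright granule
speckle, lymphocytes one round nucleus filling >= 70% of the blob, and
monocytes one kidney-shaped nucleus.  Optional salt noise flips isolated
background/erythrocyte pixels to leukocyte colors to exercise morphological
opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from scipy import ndimage

from .imageio_core import ClassLabel, LabeledDataset, Record

__all__ = [
    "SyntheticScene",
    "generate_scene",
    "generate_class_scenes",
    "generate_class_dataset",
    "nucleus_lobe_count",
]

# Color ranges (inclusive) per region; see module docstring for the margins.
BACKGROUND_RANGE = ((190, 230), (190, 230), (190, 230))
ERYTHROCYTE_RANGE = ((180, 220), (120, 160), (110, 145))
LEUKOCYTE_CYTOPLASM_RANGE = ((118, 140), (88, 110), (188, 210))
LEUKOCYTE_NUCLEUS_RANGE = ((100, 120), (60, 80), (160, 180))
GRANULE_COLOR = (135, 105, 208)
NOISE_COLOR_RANGE = ((125, 135), (95, 105), (195, 205))

#: Green-channel cut separating nucleus pixels (g <= 80) from everything
#: else in a noise-free scene (cytoplasm g >= 88, erythrocyte g >= 120,
#: background g >= 190, granules and noise g >= 95).
NUCLEUS_GREEN_CUT = 85


@dataclass
class SyntheticScene:
    """A rendered scene with its ground-truth region masks."""

    image: np.ndarray
    gt_leukocyte: np.ndarray
    gt_erythrocyte: np.ndarray
    label: ClassLabel
    seed: int


def _ellipse_mask(h: int, w: int, cy: float, cx: float,
                  ry: float, rx: float, theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(theta), math.sin(theta)
    u = (c * dx + s * dy) / rx
    v = (-s * dx + c * dy) / ry
    return u * u + v * v <= 1.0


def _fill(img: np.ndarray, mask: np.ndarray,
          ranges, rng: np.random.Generator) -> None:
    """Paint masked pixels with per-pixel colors drawn from channel ranges."""
    n = int(mask.sum())
    for ch, (lo, hi) in enumerate(ranges):
        img[..., ch][mask] = rng.integers(lo, hi + 1, size=n)


def _paint_nucleus(img: np.ndarray, blob: np.ndarray, cy: float, cx: float,
                   rmin: float, label: ClassLabel, rng: np.random.Generator) -> None:
    h, w = blob.shape
    nucleus = np.zeros_like(blob)
    if label is ClassLabel.LYMPHOCYTE:
        # one round nucleus covering ~72% of the blob (0.85^2)
        nucleus = _ellipse_mask(h, w, cy, cx, 0.85 * rmin, 0.85 * rmin)
    elif label is ClassLabel.MONOCYTE:
        body = _ellipse_mask(h, w, cy, cx, 0.72 * rmin, 0.72 * rmin)
        ang = rng.uniform(0, 2 * math.pi)
        by = cy + 0.62 * rmin * math.sin(ang)
        bx = cx + 0.62 * rmin * math.cos(ang)
        bite = _ellipse_mask(h, w, by, bx, 0.45 * rmin, 0.45 * rmin)
        nucleus = body & ~bite
    else:
        if label is ClassLabel.NEUTROPHIL:
            n_lobes = int(rng.integers(3, 6))
            lobe_r = rng.uniform(0.14, 0.19) * rmin
            dist_lo, dist_hi = 0.42, 0.55
        else:
            n_lobes = 2
            lobe_r = rng.uniform(0.28, 0.34) * rmin
            dist_lo, dist_hi = 0.38, 0.52
        # spread lobes on a ring; at 5 lobes the minimum chord
        # 2*0.42*sin(36 deg) ~ 0.49*rmin exceeds twice the maximum lobe
        # radius, so lobes stay disjoint and inside the blob
        phase = rng.uniform(0, 2 * math.pi)
        for k in range(n_lobes):
            ang = phase + 2 * math.pi * k / n_lobes
            dist = rng.uniform(dist_lo, dist_hi) * rmin
            ly = cy + dist * math.sin(ang)
            lx = cx + dist * math.cos(ang)
            nucleus |= _ellipse_mask(h, w, ly, lx, lobe_r, lobe_r)
    nucleus &= blob
    _fill(img, nucleus, LEUKOCYTE_NUCLEUS_RANGE, rng)
    if label is ClassLabel.EOSINOPHIL:
        cyto = blob & ~nucleus
        idx = np.flatnonzero(cyto.ravel())
        take = rng.choice(idx, size=max(1, int(0.10 * idx.size)), replace=False)
        flat = img.reshape(-1, 3)
        for ch, base in enumerate(GRANULE_COLOR):
            flat[take, ch] = np.clip(
                base + rng.integers(-3, 4, size=take.size), 0, 255
            )


def generate_scene(
    seed: int,
    width: int = 256,
    height: int = 192,
    n_erythrocytes: int = 10,
    noise_fraction: float = 0.01,
    label: ClassLabel | None = None,
) -> SyntheticScene:
    """Render one scene with ground-truth masks.

    ``noise_fraction`` of the non-leukocyte pixels are flipped to isolated
    leukocyte-colored singletons; ground-truth masks never include noise
    pixels.  The class (random if ``label`` is None) controls the nucleus
    morphology only.
    """
    if width < 64 or height < 64:
        raise ValueError("scenes must be at least 64x64")
    rng = np.random.default_rng(seed)
    if label is None:
        label = list(ClassLabel)[int(rng.integers(0, 4))]
    img = np.empty((height, width, 3), dtype=np.uint8)
    full = np.ones((height, width), dtype=bool)
    _fill(img, full, BACKGROUND_RANGE, rng)

    # Leukocyte geometry first, so erythrocytes can avoid it.  Leukocytes
    # dominate these close-up smear frames, so the blob radius scales with
    # the scene (0.18-0.28 of the short side; ~35-54 px at 256x192), with
    # erythrocytes roughly half that, as in real smears.
    short = min(height, width)
    rmax = 0.28 * short
    ry = rng.uniform(0.18 * short, rmax)
    rx = rng.uniform(0.18 * short, rmax)
    cy = rng.uniform(rmax + 4, height - rmax - 4)
    cx = rng.uniform(rmax + 4, width - rmax - 4)
    blob = _ellipse_mask(height, width, cy, cx, ry, rx)

    ery_lo, ery_hi = 0.07 * short, 0.12 * short
    gt_ery = np.zeros((height, width), dtype=bool)
    placed = 0
    for _ in range(50 * max(1, n_erythrocytes)):
        if placed >= n_erythrocytes:
            break
        ery_ry = rng.uniform(ery_lo, ery_hi)
        ery_rx = rng.uniform(ery_lo, ery_hi)
        ey = rng.uniform(0, height)
        ex = rng.uniform(0, width)
        if math.hypot(ey - cy, ex - cx) < rmax + ery_hi + 6.0:
            continue  # keep clear of the leukocyte
        cell = _ellipse_mask(height, width, ey, ex, ery_ry, ery_rx,
                             rng.uniform(0, math.pi))
        _fill(img, cell, ERYTHROCYTE_RANGE, rng)
        gt_ery |= cell
        placed += 1

    _fill(img, blob, LEUKOCYTE_CYTOPLASM_RANGE, rng)
    _paint_nucleus(img, blob, cy, cx, min(ry, rx), label, rng)
    gt_ery &= ~blob

    if noise_fraction > 0:
        candidates = np.flatnonzero(~blob.ravel())
        n_noise = int(round(noise_fraction * candidates.size))
        if n_noise:
            take = rng.choice(candidates, size=n_noise, replace=False)
            flat = img.reshape(-1, 3)
            for ch, (lo, hi) in enumerate(NOISE_COLOR_RANGE):
                flat[take, ch] = rng.integers(lo, hi + 1, size=n_noise)
            noise_mask = np.zeros(height * width, dtype=bool)
            noise_mask[take] = True
            gt_ery &= ~noise_mask.reshape(height, width)

    return SyntheticScene(img, blob, gt_ery, label, seed)


def generate_class_scenes(
    seed: int,
    n_per_class: int,
    width: int = 256,
    height: int = 192,
    n_erythrocytes: int = 10,
    noise_fraction: float = 0.01,
) -> list[SyntheticScene]:
    """Balanced list of scenes: ``n_per_class`` per class, class-blocked order."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    children = np.random.SeedSequence(seed).spawn(4 * n_per_class)
    scenes = []
    i = 0
    for label in ClassLabel:
        for _ in range(n_per_class):
            scene_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            scenes.append(
                generate_scene(scene_seed, width, height, n_erythrocytes,
                               noise_fraction, label)
            )
            i += 1
    return scenes


def generate_class_dataset(
    seed: int,
    n_per_class: int,
    **scene_kwargs,
) -> LabeledDataset:
    """Balanced four-class dataset of rendered scenes (images + labels)."""
    scenes = generate_class_scenes(seed, n_per_class, **scene_kwargs)
    records = [
        Record(s.image, s.label, f"{s.label.name}/synth_{i:05d}")
        for i, s in enumerate(scenes)
    ]
    return LabeledDataset(records)


def nucleus_lobe_count(img: np.ndarray, min_area: int = 8) -> int:
    """Count dark nucleus lobes by 8-connected components of green < cut.

    A deliberately simple hand-crafted baseline used to demonstrate that the
    class-specific morphology carries learnable signal (one big lobe for a
    lymphocyte, several small ones for a neutrophil).
    """
    dark = img[:, :, 1] < NUCLEUS_GREEN_CUT
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_area).sum())
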