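"""Image and dataset I/O, the canonical in-memory image model, and splitting.

Images are plain ``numpy`` arrays of shape ``(height, width, 3)`` and dtype
``uint8``, channel order **(red, green, blue)** regardless of what the decoder
natively returns.  All color rules in :mod:`leukoseg.segmentation` index
channel 0 as red, 1 as green, 2 as blue.

Datasets follow the public blood-cell layout: one subdirectory per class
(``NEUTROPHIL``, ``EOSINOPHIL``, ``LYMPHOCYTE``, ``MONOCYTE``) containing the
image files for that class.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ClassLabel",
    "Record",
    "LabeledDataset",
    "as_rgb_image",
    "read_image",
    "write_image",
    "load_dataset",
    "split_dataset",
]

#: File extensions accepted when scanning a dataset tree.
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


class ClassLabel(enum.Enum):
    """The four leukocyte classes, in the canonical evaluation order."""

    NEUTROPHIL = 0
    EOSINOPHIL = 1
    LYMPHOCYTE = 2
    MONOCYTE = 3

    @property
    def short(self) -> str:
        return {"NEUTROPHIL": "NE", "EOSINOPHIL": "EO",
                "LYMPHOCYTE": "LM", "MONOCYTE": "MN"}[self.name]


#: Labels ordered by index — the row/column order of every confusion matrix.
CLASS_ORDER = tuple(ClassLabel)


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate and return ``arr`` as an RGB image array.

    Raises
    ------
    ValueError
        If the array is not ``(H, W, 3)`` uint8 with ``H, W >= 1``.
    """
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be at least 1x1, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(f"expected uint8 intensities in [0, 255], got dtype {arr.dtype}")
    return arr


@dataclass(frozen=True)
class Record:
    """One labeled image. ``name`` is unique within a dataset."""

    image: np.ndarray
    label: ClassLabel
    name: str

    def __post_init__(self):
        object.__setattr__(self, "image", as_rgb_image(self.image))


@dataclass
class LabeledDataset:
    """An ordered collection of labeled images with unique names."""

    records: list[Record] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate record names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[ClassLabel]:
        return [r.label for r in self.records]

    def count_per_class(self) -> dict[ClassLabel, int]:
        counts = {label: 0 for label in CLASS_ORDER}
        for r in self.records:
            counts[r.label] += 1
        return counts


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file into an ``(H, W, 3)`` uint8 RGB array.

    Pillow decodes into RGB order already; grayscale and paletted inputs are
    expanded to three channels, alpha is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path!s}: {exc}") from exc


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB array to ``path``; format inferred from the suffix."""
    img = as_rgb_image(img)
    Image.fromarray(img, mode="RGB").save(Path(path))


def load_dataset(root_dir: str | Path) -> LabeledDataset:
    """Load a class-per-subdirectory tree into a :class:`LabeledDataset`.

    Record order is deterministic: classes in ``CLASS_ORDER``, files sorted by
    name within each class.  Unknown subdirectory names raise; an empty class
    directory only warns.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise IOError(f"dataset root {root!s} is not a directory")
    by_name = {label.name: label for label in CLASS_ORDER}
    subdirs = sorted(p.name for p in root.iterdir() if p.is_dir())
    unknown = [d for d in subdirs if d not in by_name]
    if unknown:
        raise ValueError(
            f"unknown class subdirectories under {root!s}: {unknown}; "
            f"expected a subset of {sorted(by_name)}"
        )
    records: list[Record] = []
    for label in CLASS_ORDER:
        class_dir = root / label.name
        if not class_dir.is_dir():
            continue
        files = sorted(
            p for p in class_dir.iterdir()
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            warnings.warn(f"class directory {class_dir!s} contains no images")
        for p in files:
            records.append(Record(read_image(p), label, f"{label.name}/{p.name}"))
    return LabeledDataset(records)


def split_dataset(
    dataset: LabeledDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffle and split into train/test partitions.

    The train share is ``floor(train_fraction * n)`` (12,444 records at 0.8
    give 9,955 / 2,489); the shuffle is a pure function of ``seed``.  With
    ``stratify=True`` the floor rule is applied per class instead.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[int] = []
        test_idx: list[int] = []
        labels = dataset.labels()
        for label in CLASS_ORDER:
            idx = np.flatnonzero([lab == label for lab in labels])
            idx = rng.permutation(idx)
            k = math.floor(train_fraction * len(idx))
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        train_idx.sort()
        test_idx.sort()
    else:
        perm = rng.permutation(n)
        k = math.floor(train_fraction * n)
        train_idx, test_idx = list(perm[:k]), list(perm[k:])
    train = LabeledDataset([dataset.records[i] for i in train_idx])
    test = LabeledDataset([dataset.records[i] for i in test_idx])
    return train, test
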