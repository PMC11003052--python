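"""Confusion-matrix construction and agreement statistics.

Rows index the true class, columns the predicted class, both in the order
(NEUTROPHIL, EOSINOPHIL, LYMPHOCYTE, MONOCYTE).  Per-class metrics treat
each class one-vs-rest; 0/0 ratios are reported as ``None`` with a warning
rather than silently coerced to 0, and macro averages skip them.

Cohen's kappa corrects observed agreement PO = trace/total for the chance
agreement PE = sum_c (row_c/total)(col_c/total):

    K = (PO - PE) / (1 - PE)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .imageio_core import CLASS_ORDER, ClassLabel

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "cohens_kappa",
    "mask_iou",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table, rows = truth, columns = prediction."""

    counts: np.ndarray
    labels: tuple[ClassLabel, ...] = CLASS_ORDER

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus overall agreement statistics.

    Per-class entries are ``None`` where the defining ratio is 0/0.
    """

    precision: list[Optional[float]]
    sensitivity: list[Optional[float]]
    specificity: list[Optional[float]]
    f1: list[Optional[float]]
    accuracy: float
    kappa: Optional[float]  # None when chance agreement PE = 1
    observed_agreement: float
    chance_agreement: float
    labels: tuple[ClassLabel, ...] = CLASS_ORDER

    def macro(self, metric: str) -> float:
        """Unweighted mean of a per-class metric, skipping undefined entries."""
        values = [v for v in getattr(self, metric) if v is not None]
        if not values:
            raise ValueError(f"all per-class values of {metric!r} are undefined")
        return float(np.mean(values))

    def as_dict(self) -> dict:
        return {
            "per_class": {
                lab.name: {
                    "precision": self.precision[i],
                    "sensitivity": self.sensitivity[i],
                    "specificity": self.specificity[i],
                    "f1": self.f1[i],
                }
                for i, lab in enumerate(self.labels)
            },
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "chance_agreement": self.chance_agreement,
        }


def _as_indices(y: Sequence, k: int) -> np.ndarray:
    out = np.array(
        [lab.value if isinstance(lab, ClassLabel) else int(lab) for lab in y],
        dtype=np.int64,
    )
    if out.size and not ((0 <= out) & (out < k)).all():
        raise ValueError(f"labels must be in [0, {k})")
    return out


def confusion(y_true: Sequence, y_pred: Sequence,
              labels: tuple[ClassLabel, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Count table ``counts[i, j] = #{true == i and pred == j}``."""
    k = len(labels)
    t = _as_indices(y_true, k)
    p = _as_indices(y_pred, k)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, labels)


def _safe_ratio(num: float, den: float, what: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{what} is undefined (0/0); reporting None")
        return None
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/sensitivity/specificity/F1 plus accuracy and kappa."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    precision, sensitivity, specificity, f1 = [], [], [], []
    for i, lab in enumerate(cm.labels):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        tn = total - tp - fp - fn
        prec = _safe_ratio(tp, tp + fp, f"precision[{lab.name}]")
        sens = _safe_ratio(tp, tp + fn, f"sensitivity[{lab.name}]")
        spec = _safe_ratio(tn, tn + fp, f"specificity[{lab.name}]")
        if prec is None or sens is None or prec + sens == 0:
            f1_val = None
            if prec is not None and sens is not None:
                warnings.warn(f"f1[{lab.name}] is undefined (0/0); reporting None")
        else:
            f1_val = 2 * prec * sens / (prec + sens)
        precision.append(prec)
        sensitivity.append(sens)
        specificity.append(spec)
        f1.append(f1_val)
    po = cm.trace / total
    pe = float(((counts.sum(axis=1) / total) * (counts.sum(axis=0) / total)).sum())
    if pe >= 1.0:
        warnings.warn("kappa is undefined (chance agreement PE = 1); reporting None")
        kappa = None
    else:
        kappa = cohens_kappa(cm)
    return MetricsReport(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        accuracy=po,
        kappa=kappa,
        observed_agreement=po,
        chance_agreement=pe,
        labels=cm.labels,
    )


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement K = (PO - PE) / (1 - PE)."""
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute kappa for an empty confusion matrix")
    po = cm.trace / total
    row = cm.counts.sum(axis=1) / total
    col = cm.counts.sum(axis=0) / total
    pe = float((row * col).sum())
    if pe >= 1.0:
        raise ValueError("kappa is undefined when chance agreement PE = 1")
    return float((po - pe) / (1.0 - pe))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 if both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
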