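"""Reconstruction and classification evaluation indices.

MSE / PSNR for volume reconstruction; confusion matrix with one-vs-rest
precision, recall and F1 per class plus macro averages for classification.
The binary precision/recall definitions are extended to the multi-class
case one-vs-rest; a zero denominator (no predicted or no true samples of a
class) yields metric 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["mse", "psnr", "confusion_matrix", "classification_report",
           "ClassificationReport"]


def _vol(a) -> np.ndarray:
    from .moments import VoxelGrid

    return a.data if isinstance(a, VoxelGrid) else np.asarray(a, dtype=float)


def mse(f, fhat) -> float:
    """Mean squared voxel difference; 0 iff the volumes are identical."""
    a, b = _vol(f), _vol(fhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(f, fhat, L: float = 255.0) -> float:
    """``10 log10(L^2 / MSE)`` in dB; ``inf`` for identical volumes."""
    e = mse(f, fhat)
    if e == 0.0:
        return float("inf")
    return float(10.0 * np.log10(L * L / e))


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Counts ``C[i, j]`` of samples with true class i predicted as j."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    k = n_classes if n_classes is not None else int(max(t.max(), p.max())) + 1
    C = np.zeros((k, k), dtype=int)
    np.add.at(C, (t, p), 1)
    return C


@dataclass(frozen=True)
class ClassificationReport:
    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def summary(self) -> str:
        lines = [
            f"accuracy          {self.accuracy:.4f}",
            f"macro precision   {self.macro_precision:.4f}",
            f"macro recall      {self.macro_recall:.4f}",
            f"macro F1          {self.macro_f1:.4f}",
            "class  precision  recall     F1",
        ]
        for c, (p, r, f) in enumerate(zip(self.precision, self.recall, self.f1)):
            lines.append(f"{c:5d}  {p:9.4f}  {r:6.4f}  {f:6.4f}")
        return "\n".join(lines)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not np.all(ok):
        warnings.warn(
            f"{what} undefined for classes {np.nonzero(~ok)[0].tolist()}; set to 0",
            stacklevel=3,
        )
    return out


def classification_report(y_true, y_pred, n_classes: int | None = None) -> ClassificationReport:
    """Accuracy ``T/N`` plus one-vs-rest precision/recall/F1 per class."""
    C = confusion_matrix(y_true, y_pred, n_classes)
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "F1")
    return ClassificationReport(
        confusion=C,
        accuracy=float(tp.sum() / C.sum()),
        precision=precision,
        recall=recall,
        f1=f1,
    )
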