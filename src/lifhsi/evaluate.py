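"""Ground-truth handling, confusion counting and spatial error maps.

The positive class throughout is "contaminated" (code 1).  Ground-truth
hygiene follows the usual recipe for pixel-wise validation of segmentation
maps: mixed boundary pixels are discarded by a 1-pixel morphological erosion
of the contaminated region, and balanced per-class subsets are drawn without
replacement for statistics that must not be dominated by class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .cube_io import CLEAN, CONTAMINATED, UNLABELED, HSCube, LabelMask
from .preprocess import SpectrumMatrix

__all__ = [
    "ROISpec",
    "ConfusionCounts",
    "MetricsReport",
    "ERROR_MAP_PALETTE",
    "extract_roi",
    "erode_mask",
    "balanced_sample",
    "confusion",
    "metrics",
    "counts_from_precision_recall",
    "class_fraction",
    "error_map",
]

#: RGB palette of the spatial error map.
ERROR_MAP_PALETTE = {
    "TP": (0, 0, 255),     # blue: correctly detected contamination
    "TN": (0, 255, 0),     # green: correctly identified clean salt
    "FP": (255, 255, 0),   # yellow: over-detection
    "FN": (255, 0, 0),     # red: missed contamination
    "unlabeled": (0, 0, 0),
}


@dataclass(frozen=True)
class ROISpec:
    """Fixed rectangular window used to harvest labeled training spectra.

    ``origin`` follows the imaging-software convention (x = column,
    y = row) by default; set ``origin_is_xy=False`` if the origin is already
    (row, col).  The window is half-open: ``width * height`` pixels starting
    at the origin.
    """

    origin: tuple[int, int]
    width: int = 30
    height: int = 30
    label: int = CLEAN
    origin_is_xy: bool = True

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI dimensions must be >= 1")

    @property
    def row0(self) -> int:
        return self.origin[1] if self.origin_is_xy else self.origin[0]

    @property
    def col0(self) -> int:
        return self.origin[0] if self.origin_is_xy else self.origin[1]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN over the labeled pixels of a comparison."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1 as fractions in [0, 1].

    A metric whose denominator is zero (e.g. precision with no predicted
    positives) is reported as ``None`` with the corresponding flag in
    ``undefined`` — never silently coerced to 0 or 1.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    counts: ConfusionCounts

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, value in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            )
            if value is None
        )

    def as_percent(self) -> dict:
        """Export formatting: accuracy in % (2 dp), the rest to 4 dp."""
        fmt = lambda v, nd: None if v is None else round(v, nd)
        return {
            "accuracy_pct": round(self.accuracy * 100.0, 2),
            "precision": fmt(self.precision, 4),
            "recall": fmt(self.recall, 4),
            "f1": fmt(self.f1, 4),
        }


def extract_roi(cube: HSCube, roi: ROISpec) -> SpectrumMatrix:
    """Spectra of all pixels inside the ROI, labeled per ``roi.label``."""
    r0, c0 = roi.row0, roi.col0
    r1, c1 = r0 + roi.height, c0 + roi.width
    if r0 < 0 or c0 < 0 or r1 > cube.rows or c1 > cube.cols:
        raise IndexError(
            f"ROI rows {r0}:{r1} cols {c0}:{c1} exceeds cube "
            f"{cube.rows}x{cube.cols}"
        )
    block = cube.data[r0:r1, c0:c1, :].reshape(-1, cube.bands)
    labels = np.full(block.shape[0], roi.label)
    return SpectrumMatrix(block, cube.grid, labels)


def erode_mask(mask: LabelMask, radius: int = 1) -> LabelMask:
    """Erode the contaminated region to discard mixed boundary pixels.

    The structuring element is the (2*radius+1)-square (8-connectivity for
    radius 1); the image border counts as background, so contaminated pixels
    touching the border are always removed.  Eroded-away pixels become
    unlabeled (255) rather than clean — they are ambiguous, not clean.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return LabelMask(mask.labels.copy())
    contaminated = mask.labels == CONTAMINATED
    selem = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    core = binary_erosion(contaminated, structure=selem, border_value=0)
    out = mask.labels.copy()
    out[contaminated & ~core] = UNLABELED
    return LabelMask(out)


def balanced_sample(
    mask: LabelMask, n_per_class: int, seed: int | None = None
) -> list[tuple[int, int, int]]:
    """Draw ``n_per_class`` pixels per class uniformly without replacement.

    Returns ``(row, col, label)`` triples, clean pixels first, each class in
    a reproducible order under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int, int]] = []
    for code in (CLEAN, CONTAMINATED):
        rows, cols = np.nonzero(mask.labels == code)
        if rows.size < n_per_class:
            name = "clean" if code == CLEAN else "contaminated"
            raise ValueError(
                f"class {name!r} has only {rows.size} labeled pixels, "
                f"{n_per_class} requested"
            )
        idx = rng.choice(rows.size, size=n_per_class, replace=False)
        out.extend((int(rows[i]), int(cols[i]), code) for i in idx)
    return out


def _categories(pred: LabelMask, truth: LabelMask):
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    labeled = truth.labeled()
    p = pred.labels == CONTAMINATED
    t = truth.labels == CONTAMINATED
    return {
        "TP": labeled & p & t,
        "TN": labeled & ~p & ~t,
        "FP": labeled & p & ~t,
        "FN": labeled & ~p & t,
    }


def confusion(pred: LabelMask, truth: LabelMask) -> ConfusionCounts:
    """Count TP/TN/FP/FN over all truth-labeled pixels (255 excluded)."""
    cats = _categories(pred, truth)
    return ConfusionCounts(
        tp=int(cats["TP"].sum()),
        tn=int(cats["TN"].sum()),
        fp=int(cats["FP"].sum()),
        fn=int(cats["FN"].sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from raw counts.

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    """
    if c.total == 0:
        raise ValueError("empty comparison: all counts are zero")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricsReport(accuracy, precision, recall, f1, c)


def counts_from_precision_recall(
    precision: float, recall: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed precision/recall.

    For a balanced evaluation set with ``n_pos`` positive and ``n_neg``
    negative pixels: TP = recall * n_pos, FN = n_pos - TP, and FP follows
    from the precision; each is rounded to the nearest integer.
    """
    if not (0 < precision <= 1 and 0 < recall <= 1):
        raise ValueError("precision and recall must lie in (0, 1]")
    tp = int(round(recall * n_pos))
    fn = n_pos - tp
    fp = int(round(tp * (1.0 - precision) / precision))
    if fp > n_neg:
        raise ValueError("implied FP exceeds the negative class size")
    return ConfusionCounts(tp=tp, tn=n_neg - fp, fp=fp, fn=fn)


def class_fraction(mask: LabelMask, include_unlabeled: bool = False) -> dict:
    """Fraction of pixels per class.

    By default fractions are taken over labeled pixels only; with
    ``include_unlabeled=True`` the denominator is the full raster (then the
    two fractions need not sum to 1).
    """
    total = mask.labels.size if include_unlabeled else int(mask.labeled().sum())
    if total == 0:
        raise ValueError("mask has no labeled pixels")
    return {
        "clean": float(np.sum(mask.labels == CLEAN)) / total,
        "contaminated": float(np.sum(mask.labels == CONTAMINATED)) / total,
    }


def error_map(pred: LabelMask, truth: LabelMask) -> np.ndarray:
    """Color-coded rows x cols x 3 uint8 raster of the spatial comparison.

    TP blue, TN green, FP yellow, FN red, unlabeled black; category pixel
    counts agree with :func:`confusion` by construction.
    """
    cats = _categories(pred, truth)
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    for name, where in cats.items():
        out[where] = ERROR_MAP_PALETTE[name]
    return out
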