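"""Pixel-overlap metrics between a reference and a predicted mask.

Pixels inside a region of interest are classified against the reference:

* TP — marked as the target class (coronary, by default) in both masks,
* FP — target class only in the predicted mask,
* TN — background with respect to the target class in both masks,
* FN — target class only in the reference mask,

and seven derived metrics are reported::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    ppv         = TP / (TP + FP)
    npv         = TN / (TN + FN)
    iou         = TP / (TP + FN + FP)
    dice        = 2 TP / (2 TP + FN + FP)

Dice and IoU obey the identity D = 2J / (1 + J).  A metric whose denominator
is zero is *undefined* and reported as NaN (never silently as 0), with a
warning; downstream statistics treat it as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .caliper import QcaReference, VESSEL_ROLES
from .errors import DomainError, InvalidInputError
from .masks import CORONARY, SegmentationMask, require_same_grid

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "iou", "dice")


@dataclass(frozen=True)
class Roi:
    """Half-open pixel bounds [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise InvalidInputError("ROI is empty")
        if self.row_min < 0 or self.col_min < 0:
            raise InvalidInputError("ROI extends beyond canvas")

    @property
    def n_pixels(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    @classmethod
    def whole_image(cls, shape: tuple[int, int]) -> "Roi":
        return cls(0, shape[0], 0, shape[1])


@dataclass(frozen=True)
class OverlapCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class OverlapMetrics:
    """The seven overlap metrics as fractions in [0, 1] (NaN = undefined)."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    iou: float
    dice: float

    def as_percent_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) * 100.0 for name in METRIC_NAMES}


def roi_from_markers(
    ref: QcaReference, padding: int = 10, canvas: tuple[int, int] | None = None
) -> Roi:
    """Bounding box of the vessel marker endpoints, padded and clipped.

    The region of interest of a QCA validation is the analysed lesion zone;
    with the exact reference construction unavailable, the marker bounding
    box plus padding is used and reported explicitly.
    """
    pts = []
    for role in VESSEL_ROLES:
        m = ref.marker(role)
        pts.append(m.p0)
        pts.append(m.p1)
    arr = np.asarray(pts, float)
    row_min = int(np.floor(arr[:, 0].min())) - padding
    row_max = int(np.ceil(arr[:, 0].max())) + 1 + padding
    col_min = int(np.floor(arr[:, 1].min())) - padding
    col_max = int(np.ceil(arr[:, 1].max())) + 1 + padding
    if canvas is not None:
        row_min = max(row_min, 0)
        col_min = max(col_min, 0)
        row_max = min(row_max, canvas[0])
        col_max = min(col_max, canvas[1])
    else:
        row_min = max(row_min, 0)
        col_min = max(col_min, 0)
    return Roi(row_min, row_max, col_min, col_max)


def classify(
    reference_mask: SegmentationMask,
    predicted_mask: SegmentationMask,
    roi: Roi,
    class_label: int = CORONARY,
) -> OverlapCounts:
    """TP/FP/TN/FN pixel counts for one class within the ROI."""
    require_same_grid(reference_mask, predicted_mask)
    rows, cols = reference_mask.shape
    if roi.row_max > rows or roi.col_max > cols:
        raise InvalidInputError(f"ROI {roi} exceeds canvas {reference_mask.shape}")
    sl = (slice(roi.row_min, roi.row_max), slice(roi.col_min, roi.col_max))
    ref = reference_mask.labels[sl] == class_label
    pred = predicted_mask.labels[sl] == class_label
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(~ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    tn = int(np.count_nonzero(~ref & ~pred))
    return OverlapCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: OverlapCounts) -> OverlapMetrics:
    """The seven overlap metrics from raw counts (fractions, NaN = undefined)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise DomainError("all overlap counts are zero")
    return OverlapMetrics(
        accuracy=_ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        ppv=_ratio(tp, tp + fp, "ppv"),
        npv=_ratio(tn, tn + fn, "npv"),
        iou=_ratio(tp, tp + fn + fp, "iou"),
        dice=_ratio(2 * tp, 2 * tp + fn + fp, "dice"),
    )


def dice_from_iou(iou: float) -> float:
    """Dice implied by an IoU value via D = 2J / (1 + J) (fractions)."""
    if not 0 <= iou <= 1:
        raise DomainError("iou must be a fraction in [0, 1]")
    return 2.0 * iou / (1.0 + iou)


def dice_coefficient(
    reference_mask: SegmentationMask,
    predicted_mask: SegmentationMask,
    class_label: int = CORONARY,
) -> float:
    """Whole-image Dice for one class (convenience for calibration)."""
    counts = classify(
        reference_mask, predicted_mask, Roi.whole_image(reference_mask.shape), class_label
    )
    return metrics(counts).dice
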