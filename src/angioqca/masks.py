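"""Label masks for angiographic segmentation.

A mask is a 2-D grid of class labels over the angiogram canvas:
``0`` background, ``1`` coronary tree, ``2`` catheter — the three classes a
coronary segmentation model emits (coronary rendered white, catheter a
distinct shade).  Pixel spacing is isotropic, in mm per pixel.

Coordinate convention (used everywhere in this package): 0-based
``(row, col)``, pixel centers at integer coordinates; a pixel belongs to a
class when its center lies inside the analytic shape.

Masks persist as single-channel 8-bit PNG with gray values 0 (background),
255 (coronary) and 128 (catheter) — lossless and diff-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidInputError

BACKGROUND = 0
CORONARY = 1
CATHETER = 2

#: label -> 8-bit gray value used on disk
PNG_GRAY = {BACKGROUND: 0, CORONARY: 255, CATHETER: 128}
_GRAY_TO_LABEL = {v: k for k, v in PNG_GRAY.items()}


@dataclass
class SegmentationMask:
    """A 2-D label grid plus its physical pixel spacing.

    Parameters
    ----------
    labels : ndarray of uint8, shape (rows, cols)
        Class labels drawn from {0, 1, 2}.
    pixel_spacing : float
        Isotropic pixel size in mm/pixel; must be positive.
    """

    labels: np.ndarray
    pixel_spacing: float = 0.2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise InvalidInputError("mask labels must be a 2-D array")
        if not np.isin(self.labels, (BACKGROUND, CORONARY, CATHETER)).all():
            raise InvalidInputError("mask contains labels outside {0, 1, 2}")
        if not self.pixel_spacing > 0:
            raise InvalidInputError("pixel_spacing must be > 0 mm/px")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_mask(self, label: int) -> np.ndarray:
        """Boolean mask of one class."""
        return self.labels == label

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.labels.copy(), self.pixel_spacing)

    # ---------------------------------------------------------------- I/O
    def save_png(self, path: str | Path) -> None:
        """Write the mask as 8-bit grayscale PNG (0/255/128 encoding)."""
        gray = np.zeros_like(self.labels)
        for label, value in PNG_GRAY.items():
            gray[self.labels == label] = value
        Image.fromarray(gray, mode="L").save(Path(path), format="PNG")

    @classmethod
    def load_png(cls, path: str | Path, pixel_spacing: float) -> "SegmentationMask":
        """Read a mask written by :meth:`save_png`."""
        gray = np.asarray(Image.open(Path(path)).convert("L"))
        labels = np.zeros(gray.shape, dtype=np.uint8)
        unknown = np.ones(gray.shape, dtype=bool)
        for value, label in _GRAY_TO_LABEL.items():
            hit = gray == value
            labels[hit] = label
            unknown &= ~hit
        if unknown.any():
            raise InvalidInputError(
                f"PNG at {path} contains gray values outside the 0/128/255 encoding"
            )
        return cls(labels, pixel_spacing)


def require_same_grid(a: SegmentationMask, b: SegmentationMask) -> None:
    """Raise unless two masks share shape and spacing."""
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_spacing, b.pixel_spacing):
        raise InvalidInputError(
            f"pixel spacings differ: {a.pixel_spacing} vs {b.pixel_spacing}"
        )
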