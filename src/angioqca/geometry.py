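"""Analytic tube geometry behind the phantom generator.

A vessel (or catheter) is a smooth centerline plus a diameter profile along
arc length.  Centerlines are cubic splines through a handful of control
points, resampled to a fine uniform arc step so that rasterization and
arc-indexed queries (local diameter, tangent, marker placement) are simple
array lookups.

Rasterization uses a signed "tube field": for every centerline sample a disk
of the local radius is stamped and the field keeps, per pixel, the largest
value of ``radius - distance_to_sample``.  A pixel center is inside the tube
iff the field is non-negative.  With a 0.25 px arc step the union-of-disks
approximation to the true swept tube is well below raster resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .errors import InvalidSpecError

#: arc step (pixels) used when resampling centerlines
ARC_STEP_PX = 0.25


@dataclass
class Centerline:
    """A centerline resampled to uniform arc step.

    Attributes
    ----------
    points : ndarray, shape (n, 2)
        (row, col) positions at uniform arc spacing ``step_px``.
    step_px : float
        Arc distance between consecutive samples, in pixels.
    """

    points: np.ndarray
    step_px: float = ARC_STEP_PX

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def length_px(self) -> float:
        return (self.n - 1) * self.step_px

    @property
    def arc_px(self) -> np.ndarray:
        """Arc position of every sample, in pixels from the origin."""
        return np.arange(self.n) * self.step_px

    def point_at(self, s_px: float) -> np.ndarray:
        """Linear interpolation of the position at arc position ``s_px``."""
        i = np.clip(s_px / self.step_px, 0, self.n - 1)
        lo = int(np.floor(i))
        hi = min(lo + 1, self.n - 1)
        f = i - lo
        return (1 - f) * self.points[lo] + f * self.points[hi]

    def tangent_at(self, s_px: float) -> np.ndarray:
        """Unit tangent at arc position ``s_px`` (central difference)."""
        i = int(round(np.clip(s_px / self.step_px, 0, self.n - 1)))
        lo = max(i - 2, 0)
        hi = min(i + 2, self.n - 1)
        d = self.points[hi] - self.points[lo]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise InvalidSpecError("degenerate centerline: coincident samples")
        return d / norm

    def normal_at(self, s_px: float) -> np.ndarray:
        """Unit normal (tangent rotated 90°) at arc position ``s_px``."""
        t = self.tangent_at(s_px)
        return np.array([-t[1], t[0]])


def resample_centerline(control_points: np.ndarray, step_px: float = ARC_STEP_PX) -> Centerline:
    """Fit a parametric cubic spline through control points and resample it
    to uniform arc length.

    Two control points yield a straight segment; three or more a cubic
    (or quadratic) spline.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InvalidSpecError("centerline needs at least two (row, col) control points")
    if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
        raise InvalidSpecError("centerline control points contain duplicates")

    if len(pts) == 2:
        dense = np.linspace(pts[0], pts[1], 256)
    else:
        k = min(3, len(pts) - 1)
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
        u = np.linspace(0, 1, max(64 * len(pts), 256))
        dense = np.column_stack(interpolate.splev(u, tck))

    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < 2 * step_px:
        raise InvalidSpecError("centerline is shorter than two arc steps")
    n = int(np.floor(total / step_px)) + 1
    target = np.arange(n) * step_px
    rows = np.interp(target, arc, dense[:, 0])
    cols = np.interp(target, arc, dense[:, 1])
    return Centerline(np.column_stack([rows, cols]), step_px)


def stamp_tube(
    field: np.ndarray,
    centerline: Centerline,
    radii_px: np.ndarray,
    start: int = 0,
    stop: int | None = None,
) -> None:
    """Accumulate ``max(radius - distance)`` disk stamps into ``field`` for
    centerline samples ``start:stop``.  Mutates ``field`` in place."""
    rows, cols = field.shape
    pts = centerline.points
    stop = centerline.n if stop is None else stop
    for i in range(start, stop):
        r, c = pts[i]
        rad = float(radii_px[i])
        if rad <= 0:
            continue
        m = rad + 1.5
        r0, r1 = int(np.floor(r - m)), int(np.ceil(r + m)) + 1
        c0, c1 = int(np.floor(c - m)), int(np.ceil(c + m)) + 1
        r0, r1 = max(r0, 0), min(r1, rows)
        c0, c1 = max(c0, 0), min(c1, cols)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=float)[:, None]
        cc = np.arange(c0, c1, dtype=float)[None, :]
        val = rad - np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
        np.maximum(field[r0:r1, c0:c1], val, out=field[r0:r1, c0:c1])


def tube_mask(shape: tuple[int, int], centerline: Centerline, radii_px: np.ndarray) -> np.ndarray:
    """Boolean raster of one tube (pixel-center-inside rule)."""
    field = np.full(shape, -np.inf)
    stamp_tube(field, centerline, np.asarray(radii_px, dtype=float))
    return field >= 0


@dataclass
class TubeGeometry:
    """One rasterizable tube: centerline + per-sample radius in pixels."""

    centerline: Centerline
    radii_px: np.ndarray


@dataclass
class PhantomGeometry:
    """Full analytic geometry of one phantom case.

    Kept alongside the rasterized masks so that degradation operators that
    are defined in arc-length terms (collateral gaps, catheter tip gaps) can
    act without reconstructing centerlines from pixels.
    """

    main: TubeGeometry
    branches: list[TubeGeometry] = field(default_factory=list)
    catheter: TubeGeometry | None = None
    pixel_spacing: float = 0.2
    stenosis_center_mm: float = 0.0
    stenosis_length_mm: float = 0.0
    stenosis_severity: float = 0.0

    def main_tube_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return tube_mask(shape, self.main.centerline, self.main.radii_px)
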