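"""Marker-based caliper measurements on segmentation masks.

This module re-creates, on label masks, the measurement step of a QCA
validation: marker lines exported by the reference QCA system are
superimposed on the segmented image, the vessel chord under each marker is
measured, calibration converts pixels to mm, and percent diameter stenosis
follows the standard formula

    %DS = (reference diameter - lesion diameter) / reference diameter x 100.

The reference diameter cannot be re-derived from a segmentation (the mask
holds only the coronary tree and catheter), so the value recorded by the
reference system is always reused.

A marker whose chord cannot be found (a segmentation gap under the marker)
does not produce a number: the case is flagged excluded, mirroring how gap
cases are dropped from a validation study rather than imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, InvalidInputError, InvalidReferenceError
from .masks import CATHETER, CORONARY, SegmentationMask

VESSEL_ROLES = ("proximal_border", "lesion", "distal_border")
CATHETER_ROLES = ("catheter_caliper_a", "catheter_caliper_b")

#: default sampling step along a marker line, in pixels
DEFAULT_STEP_PX = 0.1
#: how far (px) from the marker midpoint to search for the vessel run
OFF_CENTER_TOL_PX = 2.0
#: offsets (px) of the parallel refinement lines used by measure_markers
REFINE_OFFSETS_PX = np.linspace(-8.0, 8.0, 33)
#: polynomial degree of the along-vessel chord-profile fit
REFINE_FIT_DEGREE = 4


@dataclass(frozen=True)
class MarkerLine:
    """A line segment in continuous pixel coordinates with a QCA role."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    role: str

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise InvalidReferenceError(f"marker '{self.role}' has coincident endpoints")
        if self.role not in VESSEL_ROLES + CATHETER_ROLES:
            raise InvalidReferenceError(f"unknown marker role '{self.role}'")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return d / np.linalg.norm(d)

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p0, float) + np.asarray(self.p1, float)) / 2.0

    def shifted(self, offset: np.ndarray) -> "MarkerLine":
        off = np.asarray(offset, float)
        return MarkerLine(tuple(self.p0 + off), tuple(self.p1 + off), self.role)


@dataclass
class QcaReference:
    """Stand-in for the reference QCA export: marker lines, the reference
    diameter, calibration, and (optionally) catheter caliper lines."""

    markers: list[MarkerLine]
    reference_diameter: float
    calibration: float
    catheter_french: int | None = None

    def __post_init__(self) -> None:
        roles = [m.role for m in self.markers]
        for role in VESSEL_ROLES:
            if roles.count(role) != 1:
                raise InvalidReferenceError(f"need exactly one '{role}' marker, got {roles.count(role)}")
        for role in CATHETER_ROLES:
            if roles.count(role) > 1:
                raise InvalidReferenceError(f"duplicate '{role}' marker")
        if not self.reference_diameter > 0:
            raise InvalidReferenceError("reference_diameter must be > 0 mm")
        if not self.calibration > 0:
            raise InvalidReferenceError("calibration must be > 0 mm/px")

    def marker(self, role: str) -> MarkerLine:
        for m in self.markers:
            if m.role == role:
                return m
        raise InvalidReferenceError(f"no marker with role '{role}'")

    @property
    def has_catheter_calipers(self) -> bool:
        roles = {m.role for m in self.markers}
        return set(CATHETER_ROLES) <= roles

    # -------------------------------------------------------------- JSON
    def to_dict(self) -> dict:
        return {
            "markers": [
                {"role": m.role, "p0": list(map(float, m.p0)), "p1": list(map(float, m.p1))}
                for m in self.markers
            ],
            "reference_diameter_mm": float(self.reference_diameter),
            "calibration_mm_per_px": float(self.calibration),
            "catheter_french": self.catheter_french,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QcaReference":
        markers = [MarkerLine(tuple(m["p0"]), tuple(m["p1"]), m["role"]) for m in d["markers"]]
        return cls(
            markers=markers,
            reference_diameter=d["reference_diameter_mm"],
            calibration=d["calibration_mm_per_px"],
            catheter_french=d.get("catheter_french"),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "QcaReference":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DiameterResult:
    """Vessel diameters (mm) measured under the three QCA markers."""

    proximal_mm: float | None
    lesion_mm: float | None
    distal_mm: float | None
    stenosis_percent: float | None
    gap_flags: dict = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None
    stenosis_negative: bool = False


@dataclass
class CatheterMeasurement:
    diameter_mm: float | None
    excluded: bool = False
    exclusion_reason: str | None = None


# ----------------------------------------------------------------- scalars
def french_to_mm(french_size: int) -> float:
    """Catheter outer diameter in mm from its French gauge (1 Fr = 1/3 mm)."""
    if french_size <= 0:
        raise DomainError("french_size must be a positive integer")
    return french_size / 3.0


def calibration_from_catheter(measured_px: float, french_size: int) -> float:
    """mm/pixel calibration from the measured catheter width in pixels."""
    if measured_px <= 0:
        raise DomainError("measured catheter width must be > 0 px")
    return french_to_mm(french_size) / measured_px


def percent_stenosis(lesion_diameter: float, reference_diameter: float) -> float:
    """Percent diameter stenosis.  May be negative when the lesion chord
    exceeds the reference diameter (reported as-is, never clamped)."""
    if reference_diameter <= 0:
        raise DomainError("reference_diameter must be > 0 mm")
    if lesion_diameter < 0:
        raise DomainError("lesion_diameter must be >= 0 mm")
    return (reference_diameter - lesion_diameter) / reference_diameter * 100.0


# ------------------------------------------------------------------ chords
def chord_length(
    mask: SegmentationMask,
    line: MarkerLine,
    class_label: int = CORONARY,
    step: float = DEFAULT_STEP_PX,
) -> float | None:
    """Length (pixels) of the in-class chord under a marker line.

    The segment is sampled at ``step`` pixel intervals; a sample is in-class
    when its nearest pixel carries ``class_label``.  The chord is the
    contiguous in-class run containing the sample nearest the segment
    midpoint; if the midpoint sample is out-of-class, the nearest in-class
    run within :data:`OFF_CENTER_TOL_PX` is used instead (markers sit on the
    reference image and may be slightly off-center on the segmented one).

    Returns ``None`` — a gap signal — when no run is found within tolerance.
    """
    if step <= 0:
        raise InvalidInputError("sampling step must be > 0 px")
    p0 = np.asarray(line.p0, float)
    p1 = np.asarray(line.p1, float)
    rows, cols = mask.shape
    for p in (p0, p1):
        if not (-0.5 <= p[0] <= rows - 0.5 and -0.5 <= p[1] <= cols - 0.5):
            raise InvalidInputError(f"marker endpoint {tuple(p)} outside canvas {mask.shape}")

    length = float(np.linalg.norm(p1 - p0))
    n = int(np.ceil(length / step)) + 1
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    actual_step = length / (n - 1)

    rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, rows - 1)
    cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, cols - 1)
    in_class = mask.labels[rr, cc] == class_label
    if not in_class.any():
        return None

    mid = (n - 1) // 2
    if in_class[mid]:
        anchor = mid
    else:
        tol = int(np.ceil(OFF_CENTER_TOL_PX / actual_step))
        anchor = None
        for d in range(1, tol + 1):
            if mid - d >= 0 and in_class[mid - d]:
                anchor = mid - d
                break
            if mid + d < n and in_class[mid + d]:
                anchor = mid + d
                break
        if anchor is None:
            return None

    lo = anchor
    while lo > 0 and in_class[lo - 1]:
        lo -= 1
    hi = anchor
    while hi < n - 1 and in_class[hi + 1]:
        hi += 1
    # midpoint rule: run of k samples covers ~k steps of the segment
    return (hi - lo + 1) * actual_step


def _refined_chord(
    mask: SegmentationMask,
    line: MarkerLine,
    class_label: int,
    step: float,
) -> float | None:
    """Sub-pixel chord at the marker position.

    A single digital chord is quantised to roughly ±1 px (and to ~0.7 px
    steps along diagonal vessels), which is too coarse for minimum-lumen
    measurements near the resolution limit.  The chord is therefore measured
    on a fan of lines parallel to the marker, offset along the local vessel
    direction, and a quartic fit of chord vs offset is evaluated at offset 0:
    averaging across the raster staircase removes most of the quantisation,
    while the polynomial absorbs the genuine diameter variation around a
    stenosis so the fit does not bias the minimum-lumen value.  Gap status
    (the exclusion signal) is decided by the central line alone, with the
    spec'd nearest-pixel rule.
    """
    center = chord_length(mask, line, class_label, step)
    if center is None:
        return None
    u = line.direction
    v = np.array([-u[1], u[0]])  # vessel direction at the marker
    rows, cols = mask.shape
    offsets, chords = [], []
    for delta in REFINE_OFFSETS_PX:
        shifted = line.shifted(delta * v)
        p0, p1 = np.asarray(shifted.p0), np.asarray(shifted.p1)
        if not all(
            -0.5 <= p[0] <= rows - 0.5 and -0.5 <= p[1] <= cols - 0.5 for p in (p0, p1)
        ):
            continue
        c = chord_length(mask, shifted, class_label, step)
        if c is not None:
            offsets.append(delta)
            chords.append(c)
    if len(chords) < REFINE_FIT_DEGREE + 3:
        return center
    coeffs = np.polyfit(offsets, chords, REFINE_FIT_DEGREE)
    fitted = float(np.polyval(coeffs, 0.0))
    # guard against ill-conditioned fits on ragged chords
    lo, hi = min(chords), max(chords)
    return float(np.clip(fitted, lo, hi))


# ------------------------------------------------------------ measurements
def measure_markers(
    mask: SegmentationMask,
    ref: QcaReference,
    step: float = DEFAULT_STEP_PX,
    refine: bool = True,
) -> DiameterResult:
    """Measure the three vessel diameters under the QCA markers and the
    percent stenosis (reusing the reference diameter from ``ref``).

    Any marker with a gap flags the case excluded; no value is imputed.
    """
    chord = _refined_chord if refine else (
        lambda m, l, cl, st: chord_length(m, l, cl, st)
    )
    diam_mm: dict[str, float | None] = {}
    gap_flags: dict[str, bool] = {}
    for role in VESSEL_ROLES:
        c = chord(mask, ref.marker(role), CORONARY, step)
        gap_flags[role] = c is None
        diam_mm[role] = None if c is None else c * ref.calibration

    excluded = any(gap_flags.values())
    reason = None
    if excluded:
        first = next(r for r in VESSEL_ROLES if gap_flags[r])
        reason = f"gap:{first.replace('_border', '')}" if first != "lesion" else "gap:lesion"

    lesion = diam_mm["lesion"]
    stenosis = None if lesion is None else percent_stenosis(lesion, ref.reference_diameter)
    return DiameterResult(
        proximal_mm=diam_mm["proximal_border"],
        lesion_mm=diam_mm["lesion"],
        distal_mm=diam_mm["distal_border"],
        stenosis_percent=stenosis,
        gap_flags=gap_flags,
        excluded=excluded,
        exclusion_reason=reason,
        stenosis_negative=bool(stenosis is not None and stenosis < 0),
    )


def caliper_distance(ref: QcaReference) -> float:
    """Catheter diameter (mm) on the reference data: the perpendicular
    distance between the two parallel caliper lines times calibration."""
    if not ref.has_catheter_calipers:
        raise InvalidReferenceError("reference has no catheter caliper lines")
    a = ref.marker("catheter_caliper_a")
    b = ref.marker("catheter_caliper_b")
    ua, ub = a.direction, b.direction
    angle = np.degrees(np.arccos(np.clip(abs(float(ua @ ub)), 0.0, 1.0)))
    if angle > 2.0:
        raise InvalidReferenceError(f"caliper lines not parallel (angle {angle:.2f} deg)")
    n = np.array([-ua[1], ua[0]])
    dist_px = abs(float((b.midpoint - a.midpoint) @ n))
    return dist_px * ref.calibration


def measure_catheter(
    mask: SegmentationMask,
    ref: QcaReference,
    step: float = DEFAULT_STEP_PX,
    refine: bool = True,
) -> CatheterMeasurement:
    """Catheter diameter on the segmented mask: the catheter-class chord
    along a probe line perpendicular to, and midway between, the two caliper
    lines.  A gap in the catheter class excludes the case."""
    ref_mm = caliper_distance(ref)  # also validates parallelism
    a = ref.marker("catheter_caliper_a")
    b = ref.marker("catheter_caliper_b")
    center = (a.midpoint + b.midpoint) / 2.0
    u = a.direction
    n = np.array([-u[1], u[0]])
    half = max(2.0 * ref_mm / ref.calibration, 6.0)
    rows, cols = mask.shape
    p0 = center - half * n
    p1 = center + half * n
    p0 = np.clip(p0, [0.0, 0.0], [rows - 1.0, cols - 1.0])
    p1 = np.clip(p1, [0.0, 0.0], [rows - 1.0, cols - 1.0])
    probe = MarkerLine(tuple(p0), tuple(p1), "catheter_caliper_a")
    c = (_refined_chord if refine else chord_length)(mask, probe, CATHETER, step)
    if c is None:
        return CatheterMeasurement(None, excluded=True, exclusion_reason="gap:catheter")
    return CatheterMeasurement(c * ref.calibration)
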