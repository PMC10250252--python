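"""Synthetic vascular phantoms with known geometry and analytic truth.

Each phantom is a coronary-like main vessel (a smooth, gently curved tube
with physiological taper), optional collateral branches, a catheter of known
French size entering at the vessel origin, and a focal stenosis: the healthy
diameter profile ``d(s) = baseline * (1 - taper * s)`` is modulated by a
raised-cosine notch that reaches a factor ``(1 - severity)`` at the lesion
center.  The analytic truth record (border diameters, lesion diameter,
reference diameter, percent stenosis) is computed from the profile, never
from pixels, so the rasterized masks can be measured against ground truth
that carries no discretisation error.

A QCA-style reference record accompanies every case: three marker lines
perpendicular to the centerline at the proximal border, lesion center and
distal border; the reference diameter; the mm/px calibration; and two
parallel catheter caliper lines tangent to the catheter edges, whose
perpendicular separation equals the catheter diameter (the quantity a
catheter-based calibration measures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .caliper import MarkerLine, QcaReference, french_to_mm, percent_stenosis
from .degrade import DegradationSpec, degrade
from .errors import InvalidSpecError
from .geometry import Centerline, PhantomGeometry, TubeGeometry, resample_centerline, stamp_tube
from .masks import BACKGROUND, CATHETER, CORONARY, SegmentationMask

#: marker half-length = max(this factor x local diameter, diameter/2 + 4 px)
MARKER_HALF_LENGTH_FACTOR = 1.5


# --------------------------------------------------------------------- specs
@dataclass(frozen=True)
class CatheterSpec:
    """A diagnostic catheter of known French size (1 Fr = 1/3 mm)."""

    french_size: int = 6
    control_points: tuple = ()
    tip_position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.french_size not in (5, 6):
            raise InvalidSpecError("catheter french_size must be 5 or 6")
        if len(self.control_points) < 2:
            raise InvalidSpecError("catheter needs at least two control points")

    @property
    def diameter_mm(self) -> float:
        return french_to_mm(self.french_size)


@dataclass(frozen=True)
class BranchSpec:
    """A collateral branch: attachment arc position (mm along the main
    centerline), diameter as a fraction of the local main diameter, and its
    own centerline control points (absolute pixel coordinates, starting at
    the attachment point)."""

    attach_arc_mm: float
    diameter_fraction: float
    control_points: tuple

    def __post_init__(self) -> None:
        if not 0 < self.diameter_fraction < 1:
            raise InvalidSpecError("branch diameter_fraction must be in (0, 1)")
        if len(self.control_points) < 2:
            raise InvalidSpecError("branch needs at least two control points")


@dataclass(frozen=True)
class VesselTreeSpec:
    """Geometry of one phantom coronary tree."""

    canvas_size: tuple[int, int] = (512, 512)
    pixel_spacing: float = 0.2
    main_centerline: tuple = ()
    baseline_diameter: float = 3.0
    taper_rate: float = 0.005
    branches: tuple = ()
    catheter: CatheterSpec | None = None

    def __post_init__(self) -> None:
        if self.canvas_size[0] < 64 or self.canvas_size[1] < 64:
            raise InvalidSpecError("canvas must be at least 64x64")
        if not self.pixel_spacing > 0:
            raise InvalidSpecError("pixel_spacing must be > 0")
        if not self.baseline_diameter > 0:
            raise InvalidSpecError("baseline_diameter must be > 0 mm")
        if self.taper_rate < 0:
            raise InvalidSpecError("taper_rate must be >= 0 per mm")
        if len(self.main_centerline) < 2:
            raise InvalidSpecError("main centerline needs at least two control points")


@dataclass(frozen=True)
class StenosisSpec:
    """A focal stenosis: center arc position (mm), fractional diameter
    reduction at its center, and lesion length (mm)."""

    arc_position: float
    severity: float
    length: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 0.99:
            raise InvalidSpecError("severity must be in [0, 0.99]")
        if not self.length >= 0:
            raise InvalidSpecError("stenosis length must be >= 0 mm")


@dataclass(frozen=True)
class TruthRecord:
    """Analytic truth diameters (mm) and percent stenosis."""

    proximal_mm: float
    lesion_mm: float
    distal_mm: float
    reference_mm: float
    stenosis_percent: float


@dataclass
class PhantomCase:
    """One paired truth/prediction phantom with its reference record."""

    truth_mask: SegmentationMask
    predicted_mask: SegmentationMask
    qca_reference: QcaReference
    truth_record: TruthRecord
    geometry: PhantomGeometry
    provenance: dict = field(default_factory=dict)
    resolution_warning: bool = False


# ----------------------------------------------------------------- profiles
def healthy_diameter_mm(tree: VesselTreeSpec, s_mm: np.ndarray | float) -> np.ndarray | float:
    """Healthy (un-notched) diameter profile, linear taper along arc length."""
    return tree.baseline_diameter * (1.0 - tree.taper_rate * np.asarray(s_mm, float))


def notch_factor(stenosis: StenosisSpec, s_mm: np.ndarray | float) -> np.ndarray | float:
    """Raised-cosine narrowing factor: 1 outside the lesion, (1 - severity)
    at its center, smooth at the borders."""
    s = np.asarray(s_mm, float)
    half = stenosis.length / 2.0
    rel = s - stenosis.arc_position
    inside = np.abs(rel) <= half
    factor = np.ones_like(s)
    if stenosis.length > 0:
        factor = np.where(
            inside,
            1.0 - stenosis.severity * np.cos(np.pi * rel / stenosis.length) ** 2,
            1.0,
        )
    return factor if factor.shape else float(factor)


# ----------------------------------------------------------------- geometry
def _check_in_canvas(points: np.ndarray, radii_px: np.ndarray, canvas: tuple[int, int], what: str) -> None:
    margin = radii_px + 0.5
    if (
        (points[:, 0] - margin < -0.5).any()
        or (points[:, 0] + margin > canvas[0] - 0.5).any()
        or (points[:, 1] - margin < -0.5).any()
        or (points[:, 1] + margin > canvas[1] - 0.5).any()
    ):
        raise InvalidSpecError(f"{what} leaves the canvas {canvas}")


def build_geometry(tree: VesselTreeSpec, stenosis: StenosisSpec) -> PhantomGeometry:
    """Resolve specs into resampled centerlines + per-sample radii (px)."""
    spacing = tree.pixel_spacing
    main_cl = resample_centerline(np.asarray(tree.main_centerline, float))
    length_mm = main_cl.length_px * spacing

    if healthy_diameter_mm(tree, length_mm) <= 0:
        raise InvalidSpecError("taper drives the main diameter to zero before the vessel ends")
    half = stenosis.length / 2.0
    if not (0.0 < stenosis.arc_position - half and stenosis.arc_position + half < length_mm):
        raise InvalidSpecError("stenosis window extends beyond the vessel arc")

    s_mm = main_cl.arc_px * spacing
    diam_mm = healthy_diameter_mm(tree, s_mm) * notch_factor(stenosis, s_mm)
    main = TubeGeometry(main_cl, np.asarray(diam_mm) / 2.0 / spacing)
    _check_in_canvas(main_cl.points, main.radii_px, tree.canvas_size, "main vessel")

    branches = []
    for b in tree.branches:
        cl = resample_centerline(np.asarray(b.control_points, float))
        base_mm = float(healthy_diameter_mm(tree, b.attach_arc_mm)) * b.diameter_fraction
        sb_mm = cl.arc_px * spacing
        bdiam = np.maximum(base_mm * (1.0 - tree.taper_rate * 2.0 * sb_mm), 0.25 * base_mm)
        tube = TubeGeometry(cl, bdiam / 2.0 / spacing)
        _check_in_canvas(cl.points, tube.radii_px, tree.canvas_size, "branch")
        branches.append(tube)

    catheter = None
    if tree.catheter is not None:
        cl = resample_centerline(np.asarray(tree.catheter.control_points, float))
        radius_px = tree.catheter.diameter_mm / 2.0 / spacing
        catheter = TubeGeometry(cl, np.full(cl.n, radius_px))
        _check_in_canvas(cl.points, catheter.radii_px, tree.canvas_size, "catheter")

    return PhantomGeometry(
        main=main,
        branches=branches,
        catheter=catheter,
        pixel_spacing=spacing,
        stenosis_center_mm=stenosis.arc_position,
        stenosis_length_mm=stenosis.length,
        stenosis_severity=stenosis.severity,
    )


def rasterize(geometry: PhantomGeometry, canvas: tuple[int, int]) -> SegmentationMask:
    """Label mask from analytic geometry (pixel-center-inside rule);
    the coronary class wins where the catheter tip meets the vessel."""
    cor_field = np.full(canvas, -np.inf)
    stamp_tube(cor_field, geometry.main.centerline, geometry.main.radii_px)
    for b in geometry.branches:
        stamp_tube(cor_field, b.centerline, b.radii_px)
    labels = np.full(canvas, BACKGROUND, dtype=np.uint8)
    if geometry.catheter is not None:
        cat_field = np.full(canvas, -np.inf)
        stamp_tube(cat_field, geometry.catheter.centerline, geometry.catheter.radii_px)
        labels[cat_field >= 0] = CATHETER
    labels[cor_field >= 0] = CORONARY
    return SegmentationMask(labels, geometry.pixel_spacing)


# ---------------------------------------------------------------- reference
def make_qca_reference(
    geometry: PhantomGeometry,
    tree: VesselTreeSpec,
    stenosis: StenosisSpec,
) -> QcaReference:
    """Marker lines + reference diameter + calibration, in the layout a QCA
    workstation exports for a measured lesion."""
    if stenosis.severity <= 0:
        raise InvalidSpecError("QCA reference requires a stenosis")
    spacing = tree.pixel_spacing
    cl = geometry.main.centerline
    canvas = tree.canvas_size
    half_len = stenosis.length / 2.0
    role_positions = {
        "proximal_border": stenosis.arc_position - half_len,
        "lesion": stenosis.arc_position,
        "distal_border": stenosis.arc_position + half_len,
    }
    markers = []
    for role, s_mm in role_positions.items():
        s_px = s_mm / spacing
        p = cl.point_at(s_px)
        n = cl.normal_at(s_px)
        d_px = float(healthy_diameter_mm(tree, s_mm)) * float(notch_factor(stenosis, s_mm)) / spacing
        # extend well beyond the truth boundary on both sides
        truth_d_px = float(healthy_diameter_mm(tree, s_mm)) / spacing
        h = max(MARKER_HALF_LENGTH_FACTOR * truth_d_px, d_px / 2.0 + 4.0)
        p0, p1 = p - h * n, p + h * n
        for q in (p0, p1):
            if not (-0.5 <= q[0] <= canvas[0] - 0.5 and -0.5 <= q[1] <= canvas[1] - 0.5):
                raise InvalidSpecError(f"{role} marker line exits the canvas")
        markers.append(MarkerLine(tuple(p0), tuple(p1), role))

    if geometry.catheter is not None:
        markers.extend(_catheter_calipers(geometry, canvas))

    reference_mm = float(healthy_diameter_mm(tree, stenosis.arc_position))
    return QcaReference(
        markers=markers,
        reference_diameter=reference_mm,
        calibration=spacing,
        catheter_french=tree.catheter.french_size if tree.catheter else None,
    )


def _catheter_calipers(geometry: PhantomGeometry, canvas: tuple[int, int]) -> list[MarkerLine]:
    """Two parallel edge lines tangent to the catheter, away from the tip."""
    tube = geometry.catheter
    cl = tube.centerline
    r_px = float(tube.radii_px[0])
    half_span = 8.0  # px of line length along the catheter axis
    for frac in (0.45, 0.35, 0.55, 0.25, 0.65):
        s_px = frac * cl.length_px
        p = cl.point_at(s_px)
        t = cl.tangent_at(s_px)
        n = cl.normal_at(s_px)
        lines = []
        ok = True
        for side, role in ((-1.0, "catheter_caliper_a"), (1.0, "catheter_caliper_b")):
            c = p + side * r_px * n
            p0, p1 = c - half_span * t, c + half_span * t
            for q in (p0, p1):
                if not (-0.5 <= q[0] <= canvas[0] - 0.5 and -0.5 <= q[1] <= canvas[1] - 0.5):
                    ok = False
            lines.append(MarkerLine(tuple(p0), tuple(p1), role))
        if ok:
            return lines
    raise InvalidSpecError("catheter caliper lines exit the canvas")


# --------------------------------------------------------------- generation
def generate_phantom(
    tree: VesselTreeSpec,
    stenosis: StenosisSpec,
    degradation: DegradationSpec,
    seed: int,
) -> PhantomCase:
    """Build one phantom case: truth mask from analytic geometry, QCA
    reference record, analytic truth record, and a degraded prediction.

    The same ``(specs, seed)`` always produce bit-identical masks.
    """
    geometry = build_geometry(tree, stenosis)
    truth = rasterize(geometry, tree.canvas_size)

    reference_mm = float(healthy_diameter_mm(tree, stenosis.arc_position))
    lesion_mm = reference_mm * (1.0 - stenosis.severity)
    record = TruthRecord(
        proximal_mm=float(healthy_diameter_mm(tree, stenosis.arc_position - stenosis.length / 2)),
        lesion_mm=lesion_mm,
        distal_mm=float(healthy_diameter_mm(tree, stenosis.arc_position + stenosis.length / 2)),
        reference_mm=reference_mm,
        stenosis_percent=percent_stenosis(lesion_mm, reference_mm),
    )

    qca = make_qca_reference(geometry, tree, stenosis) if stenosis.severity > 0 else None
    deg = replace(degradation, seed=seed)
    predicted = degrade(truth, deg, geometry)

    resolution_warning = lesion_mm / tree.pixel_spacing < 2.0
    return PhantomCase(
        truth_mask=truth,
        predicted_mask=predicted,
        qca_reference=qca,
        truth_record=record,
        geometry=geometry,
        provenance={"tree": _spec_dict(tree), "stenosis": _spec_dict(stenosis),
                    "degradation": _spec_dict(deg), "seed": int(seed)},
        resolution_warning=resolution_warning,
    )


def _spec_dict(spec) -> dict:
    def conv(v):
        if isinstance(v, (CatheterSpec, BranchSpec)):
            return _spec_dict(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return {k: conv(v) for k, v in spec.__dict__.items()}


def save_case(case: PhantomCase, directory: str | Path, stem: str) -> None:
    """Persist one case: two PNG masks + one JSON sidecar (schema v1)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    case.truth_mask.save_png(directory / f"{stem}_truth.png")
    case.predicted_mask.save_png(directory / f"{stem}_pred.png")
    sidecar = {
        "schema_version": 1,
        "qca_reference": case.qca_reference.to_dict() if case.qca_reference else None,
        "truth_record": case.truth_record.__dict__,
        "provenance": case.provenance,
        "resolution_warning": case.resolution_warning,
        "pixel_spacing_mm": case.truth_mask.pixel_spacing,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


# --------------------------------------------------- randomized case sampling
def sample_tree_and_stenosis(
    rng: np.random.Generator,
    canvas_size: tuple[int, int] = (512, 512),
    pixel_spacing: float = 0.2,
    severity_range: tuple[float, float] = (0.5, 0.9),
    baseline_diameter_range: tuple[float, float] = (2.4, 3.6),
    n_branches_range: tuple[int, int] = (1, 3),
    max_tries: int = 25,
) -> tuple[VesselTreeSpec, StenosisSpec]:
    """Draw a random, geometrically valid (tree, stenosis) pair.

    The sampler emulates a projected coronary segment: the main vessel runs
    obliquely across the canvas with a gentle sinusoidal curve, carries one
    to three collaterals, tapers distally, and hosts one focal lesion away
    from both ends.  Draws are retried until the geometry validates, so the
    caller always receives a buildable spec.
    """
    last_err: Exception | None = None
    for _ in range(max_tries):
        try:
            tree, stenosis = _draw_specs(
                rng, canvas_size, pixel_spacing, severity_range,
                baseline_diameter_range, n_branches_range,
            )
            build_geometry(tree, stenosis)  # validation
            return tree, stenosis
        except InvalidSpecError as err:  # retry with fresh draws
            last_err = err
    raise InvalidSpecError(f"could not sample a valid phantom geometry: {last_err}")


def _draw_specs(rng, canvas_size, pixel_spacing, severity_range,
                baseline_diameter_range, n_branches_range):
    rows, cols = canvas_size
    scale = min(rows, cols)
    margin = 0.12 * scale
    center = np.array([rows / 2.0, cols / 2.0]) + rng.uniform(-0.04, 0.04, 2) * scale

    theta = np.deg2rad(rng.uniform(20.0, 70.0)) * rng.choice([-1.0, 1.0])
    u = np.array([np.sin(theta), np.cos(theta)])  # (row, col) direction
    perp = np.array([-u[1], u[0]])

    half_extent = 0.36 * scale
    t = np.linspace(-half_extent, half_extent, 25)
    # large-scale sweep plus a small high-frequency tremor: projected
    # coronaries are tortuous at several scales, never ruler-straight
    amp = rng.uniform(0.02, 0.06) * scale
    freq = rng.uniform(1.0, 2.0) * np.pi / (2 * half_extent)
    phase = rng.uniform(0, 2 * np.pi)
    amp2 = rng.uniform(1.5, 3.0)
    freq2 = 2 * np.pi / rng.uniform(60.0, 110.0)
    phase2 = rng.uniform(0, 2 * np.pi)
    lateral = amp * np.sin(freq * t + phase) + amp2 * np.sin(freq2 * t + phase2)
    pts = center[None, :] + t[:, None] * u[None, :] + lateral[:, None] * perp[None, :]
    pts = np.clip(pts, margin, [rows - margin, cols - margin])

    baseline = rng.uniform(*baseline_diameter_range)
    taper = rng.uniform(0.003, 0.007)
    main_cl = resample_centerline(pts)
    length_mm = main_cl.length_px * pixel_spacing

    stenosis = StenosisSpec(
        arc_position=float(rng.uniform(0.30, 0.60) * length_mm),
        severity=float(rng.uniform(*severity_range)),
        length=float(rng.uniform(5.0, 8.0)),
    )
    # keep-out window around the lesion so branch roots never run under the
    # marker fan (a branch at a measured border would disturb a real QCA too)
    keep_lo = stenosis.arc_position - stenosis.length / 2.0 - 8.0
    keep_hi = stenosis.arc_position + stenosis.length / 2.0 + 8.0

    n_branches = int(rng.integers(n_branches_range[0], n_branches_range[1] + 1))
    branches = []
    for _ in range(n_branches):
        attach_mm = None
        for _try in range(30):
            cand = rng.uniform(0.10, 0.88) * length_mm
            if not keep_lo <= cand <= keep_hi:
                attach_mm = cand
                break
        if attach_mm is None:
            continue
        attach_pt = main_cl.point_at(attach_mm / pixel_spacing)
        tangent = main_cl.tangent_at(attach_mm / pixel_spacing)
        ang = np.deg2rad(rng.uniform(35.0, 65.0)) * rng.choice([-1.0, 1.0])
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        bdir = rot @ tangent
        blen_px = rng.uniform(15.0, 28.0) / pixel_spacing
        end = attach_pt + blen_px * bdir
        end = np.clip(end, margin * 0.6, [rows - margin * 0.6, cols - margin * 0.6])
        mid = attach_pt + 0.5 * (end - attach_pt) + rng.uniform(-0.12, 0.12) * np.linalg.norm(end - attach_pt) * np.array([-bdir[1], bdir[0]])
        # spatial keep-out: the whole branch course (canvas clipping can bend
        # it back) must stay clear of the measured lesion zone
        lo_px = max((keep_lo + 4.0) / pixel_spacing, 0.0)
        hi_px = min((keep_hi - 4.0) / pixel_spacing, main_cl.length_px)
        zone = main_cl.points[int(lo_px / main_cl.step_px): int(hi_px / main_cl.step_px) + 1]
        ts = np.linspace(0.0, 1.0, 40)[:, None]
        course = np.vstack([attach_pt + ts * (mid - attach_pt), mid + ts * (end - mid)])
        clearance = (baseline / pixel_spacing) / 2.0 + 12.0
        if len(zone) and np.min(
            np.linalg.norm(course[:, None, :] - zone[None, :, :], axis=2)
        ) < clearance:
            continue
        branches.append(BranchSpec(
            attach_arc_mm=attach_mm,
            diameter_fraction=float(rng.uniform(0.35, 0.6)),
            control_points=(tuple(attach_pt), tuple(mid), tuple(end)),
        ))

    origin = pts[0]
    edge_targets = np.array([
        [margin * 0.4, origin[1]], [rows - margin * 0.4, origin[1]],
        [origin[0], margin * 0.4], [origin[0], cols - margin * 0.4],
    ])
    entry = edge_targets[int(np.argmin(np.linalg.norm(edge_targets - origin, axis=1)))]
    mid_c = 0.5 * (entry + origin) + rng.uniform(-0.02, 0.02, 2) * scale
    catheter = CatheterSpec(
        french_size=int(rng.choice([5, 6])),
        control_points=(tuple(entry), tuple(mid_c), tuple(origin)),
        tip_position=tuple(origin),
    )

    tree = VesselTreeSpec(
        canvas_size=canvas_size,
        pixel_spacing=pixel_spacing,
        main_centerline=tuple(map(tuple, pts)),
        baseline_diameter=float(baseline),
        taper_rate=float(taper),
        branches=tuple(branches),
        catheter=catheter,
    )
    return tree, stenosis
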