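"""Caliper: chord rule, gap semantics, calibration arithmetic, and
diameter/stenosis measurement on phantoms."""

import numpy as np
import pytest

from angioqca.caliper import (
    MarkerLine,
    QcaReference,
    calibration_from_catheter,
    caliper_distance,
    chord_length,
    french_to_mm,
    measure_catheter,
    measure_markers,
    percent_stenosis,
)
from angioqca.degrade import DegradationSpec
from angioqca.errors import DomainError, InvalidReferenceError
from angioqca.masks import BACKGROUND, CATHETER, CORONARY, SegmentationMask
from angioqca.phantom import StenosisSpec, generate_phantom

from conftest import horizontal_bar_mask, straight_tree


def vline(col: float, r0: float, r1: float, role: str = "lesion") -> MarkerLine:
    return MarkerLine((r0, col), (r1, col), role)


# ------------------------------------------------------------------ chords
def test_chord_across_seven_pixel_bar():
    mask = horizontal_bar_mask(7, size=64, center_row=32.0)
    c = chord_length(mask, vline(30.0, 10.0, 54.0))
    assert c == pytest.approx(7.0, abs=0.11)


def test_chord_over_background_is_gap():
    mask = horizontal_bar_mask(7, size=64, center_row=10.0)
    assert chord_length(mask, vline(30.0, 40.0, 60.0)) is None


def test_hole_beyond_tolerance_is_gap():
    """A hole at the marker midpoint wider than twice the off-center
    tolerance yields a gap signal; a narrow hole does not."""
    mask = horizontal_bar_mask(13, size=64, center_row=32.0)
    wide = mask.copy()
    wide.labels[30:35, :] = BACKGROUND  # 5 px hole centered on row 32
    assert chord_length(wide, vline(30.0, 10.0, 54.0)) is None
    narrow = mask.copy()
    narrow.labels[31:34, :] = BACKGROUND  # 3 px hole: run found within 2 px
    assert chord_length(narrow, vline(30.0, 10.0, 54.0)) is not None


def test_chord_finds_offcenter_run():
    # bar sits 1.5 px above the marker midpoint: within the 2 px tolerance
    mask = horizontal_bar_mask(5, size=64, center_row=28.0)
    c = chord_length(mask, vline(30.0, 0.0, 61.0))
    assert c == pytest.approx(5.0, abs=0.11)


def test_straight_vessel_width_recovery_property():
    """|chord - true width| <= 1 px + step over many random widths/phases."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        w = rng.uniform(4.0, 30.0)
        phase = rng.uniform(-0.5, 0.5)
        mask = horizontal_bar_mask(w, size=96, center_row=48.0 + phase)
        c = chord_length(mask, vline(48.0, 10.0, 86.0))
        assert c is not None
        assert abs(c - w) <= 1.0 + 0.1 + 1e-9


# ---------------------------------------------------------------- scalars
@pytest.mark.parametrize("lesion,ref,expected", [(1.0, 2.0, 50.0), (2.0, 2.0, 0.0), (0.88, 2.0, 56.0)])
def test_percent_stenosis_formula(lesion, ref, expected):
    assert percent_stenosis(lesion, ref) == pytest.approx(expected)


def test_percent_stenosis_domain():
    with pytest.raises(DomainError):
        percent_stenosis(1.0, 0.0)
    with pytest.raises(DomainError):
        percent_stenosis(-0.1, 2.0)
    # oversized lesion chord: negative, returned as-is
    assert percent_stenosis(2.5, 2.0) == pytest.approx(-25.0)


@pytest.mark.parametrize("fr,mm", [(6, 2.0), (5, 5 / 3), (3, 1.0)])
def test_french_to_mm(fr, mm):
    assert french_to_mm(fr) == pytest.approx(mm)


def test_french_to_mm_domain():
    with pytest.raises(DomainError):
        french_to_mm(0)


@pytest.mark.parametrize("px,fr,expected", [(10.0, 6, 0.2), (8.0, 6, 0.25), (10.0, 5, 1 / 6)])
def test_calibration_from_catheter(px, fr, expected):
    assert calibration_from_catheter(px, fr) == pytest.approx(expected)


def test_calibration_from_catheter_domain():
    with pytest.raises(DomainError):
        calibration_from_catheter(0.0, 6)


# --------------------------------------------------------- marker measurement
def test_measure_markers_recovers_straight_phantom(straight_phantom):
    res = measure_markers(straight_phantom.truth_mask, straight_phantom.qca_reference)
    tr = straight_phantom.truth_record
    assert not res.excluded
    assert res.stenosis_percent == pytest.approx(tr.stenosis_percent, abs=5.0)
    assert res.proximal_mm == pytest.approx(tr.proximal_mm, abs=0.2)
    assert res.lesion_mm == pytest.approx(tr.lesion_mm, abs=0.2)
    assert res.distal_mm == pytest.approx(tr.distal_mm, abs=0.2)
    # stored stenosis consistent with stored lesion + reference
    assert res.stenosis_percent == pytest.approx(
        percent_stenosis(res.lesion_mm, straight_phantom.qca_reference.reference_diameter),
        abs=1e-9,
    )


def test_identical_masks_give_identical_measurements(random_phantom):
    ref = random_phantom.qca_reference
    a = measure_markers(random_phantom.truth_mask, ref)
    b = measure_markers(random_phantom.truth_mask.copy(), ref)
    assert (a.proximal_mm, a.lesion_mm, a.distal_mm, a.stenosis_percent) == (
        b.proximal_mm, b.lesion_mm, b.distal_mm, b.stenosis_percent)


def test_gap_at_lesion_marker_excludes_case(straight_phantom):
    mask = straight_phantom.truth_mask.copy()
    m = straight_phantom.qca_reference.marker("lesion")
    col = int(round(m.p0[1]))
    mask.labels[:, col - 6: col + 7] = BACKGROUND  # destroy the lesion zone
    res = measure_markers(mask, straight_phantom.qca_reference)
    assert res.excluded
    assert res.exclusion_reason == "gap:lesion"
    assert res.gap_flags["lesion"]
    assert res.lesion_mm is None and res.stenosis_percent is None


def test_missing_marker_role_is_invalid():
    markers = [MarkerLine((0, 0), (0, 10), "lesion")]
    with pytest.raises(InvalidReferenceError):
        QcaReference(markers=markers, reference_diameter=2.0, calibration=0.2)


# ----------------------------------------------------------------- catheter
def _catheter_ref(dist_px: float, angle_b_deg: float = 0.0, calibration: float = 0.2):
    """Two caliper lines along rows, separated by dist_px columns... built in
    a 64x64 frame around row 32."""
    a = MarkerLine((20.0, 30.0), (44.0, 30.0), "catheter_caliper_a")
    th = np.deg2rad(angle_b_deg)
    d = np.array([np.cos(th), np.sin(th)]) * 12.0
    c = np.array([32.0, 30.0 + dist_px])
    b = MarkerLine(tuple(c - d), tuple(c + d), "catheter_caliper_b")
    vessel = [
        MarkerLine((1.0, 1.0), (1.0, 5.0), "proximal_border"),
        MarkerLine((2.0, 1.0), (2.0, 5.0), "lesion"),
        MarkerLine((3.0, 1.0), (3.0, 5.0), "distal_border"),
    ]
    return QcaReference(markers=vessel + [a, b], reference_diameter=2.0,
                        calibration=calibration, catheter_french=6)


def test_caliper_distance_parallel_lines():
    assert caliper_distance(_catheter_ref(10.0)) == pytest.approx(2.0)


def test_caliper_lines_not_parallel_rejected():
    with pytest.raises(InvalidReferenceError):
        caliper_distance(_catheter_ref(10.0, angle_b_deg=5.0))


def test_measure_catheter_gap_excludes():
    labels = np.zeros((64, 64), dtype=np.uint8)
    mask = SegmentationMask(labels, 0.2)
    res = measure_catheter(mask, _catheter_ref(10.0))
    assert res.excluded and res.exclusion_reason == "gap:catheter"


def test_measure_catheter_on_phantom(straight_phantom):
    """6 Fr truth catheter measures 2.0 mm within one pixel's worth."""
    ref = straight_phantom.qca_reference
    assert ref.catheter_french == 6
    res = measure_catheter(straight_phantom.truth_mask, ref)
    assert not res.excluded
    spacing = straight_phantom.truth_mask.pixel_spacing
    assert res.diameter_mm == pytest.approx(2.0, abs=spacing)
    # reference-side measurement is the analytic separation
    assert caliper_distance(ref) == pytest.approx(2.0, abs=1e-6)


def test_catheter_calibration_round_trip():
    """calibration_from_catheter(measured chord, Fr) recovers the true
    pixel spacing within 10% across phantoms."""
    for seed, fr in ((1, 5), (2, 6)):
        tree = straight_tree(canvas=192, french=fr)
        case = generate_phantom(tree, StenosisSpec(14.0, 0.6, 6.0), DegradationSpec(), seed=seed)
        ref = case.qca_reference
        res = measure_catheter(case.truth_mask, ref)
        cal = calibration_from_catheter(res.diameter_mm / ref.calibration, fr)
        assert cal == pytest.approx(tree.pixel_spacing, rel=0.10)
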