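"""Phantom generator: determinism, analytic-raster agreement, truth records,
degradation operators and Dice calibration."""

import numpy as np
import pytest

from angioqca.degrade import DegradationSpec, calibrate_to_dice, degrade
from angioqca.errors import ConvergenceError, DomainError, InvalidSpecError
from angioqca.masks import BACKGROUND, CATHETER, CORONARY, SegmentationMask
from angioqca.overlap import dice_coefficient
from angioqca.phantom import (
    BranchSpec,
    StenosisSpec,
    VesselTreeSpec,
    build_geometry,
    generate_phantom,
    make_qca_reference,
    rasterize,
    sample_tree_and_stenosis,
)

from conftest import straight_tree


# ------------------------------------------------------------- determinism
def test_same_specs_and_seed_give_bit_identical_cases(tmp_path):
    rng_spec = lambda: sample_tree_and_stenosis(np.random.default_rng(3), canvas_size=(256, 256))
    deg = DegradationSpec(boundary_jitter_sigma=1.0, collateral_gap_rate=0.5,
                          fp_blob_rate=1.0, catheter_gap_rate=0.5)
    tree1, st1 = rng_spec()
    tree2, st2 = rng_spec()
    assert tree1 == tree2 and st1 == st2
    a = generate_phantom(tree1, st1, deg, seed=42)
    b = generate_phantom(tree2, st2, deg, seed=42)
    assert np.array_equal(a.truth_mask.labels, b.truth_mask.labels)
    assert np.array_equal(a.predicted_mask.labels, b.predicted_mask.labels)
    assert a.qca_reference.to_dict() == b.qca_reference.to_dict()
    # byte-identical files on disk
    a.predicted_mask.save_png(tmp_path / "a.png")
    b.predicted_mask.save_png(tmp_path / "b.png")
    assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()


def test_mask_png_roundtrip(tmp_path, random_phantom):
    p = tmp_path / "m.png"
    random_phantom.truth_mask.save_png(p)
    back = SegmentationMask.load_png(p, random_phantom.truth_mask.pixel_spacing)
    assert np.array_equal(back.labels, random_phantom.truth_mask.labels)


# --------------------------------------------------- analytic-raster width
@pytest.mark.parametrize("width_px", [4, 7, 11, 16, 23, 30])
def test_straight_vessel_raster_width_matches_analytic(width_px):
    """Brute-force column scan of a straight untapered vessel recovers the
    analytic width within one pixel."""
    spacing = 0.2
    tree = straight_tree(canvas=128, diameter_mm=width_px * spacing, spacing=spacing)
    geo = build_geometry(tree, StenosisSpec(arc_position=10.0, severity=0.0, length=2.0))
    mask = rasterize(geo, tree.canvas_size)
    cols = range(45, 85)
    widths = [int(np.sum(mask.labels[:, c] == CORONARY)) for c in cols]
    assert all(abs(w - width_px) <= 1 for w in widths)


# ------------------------------------------------------------ truth record
def test_truth_record_definitional_identities():
    tree = straight_tree(canvas=192, diameter_mm=2.0, taper=0.0)
    case = generate_phantom(tree, StenosisSpec(14.0, 0.5, 6.0), DegradationSpec(), seed=1)
    tr = case.truth_record
    assert tr.reference_mm == pytest.approx(2.0)
    assert tr.lesion_mm == pytest.approx(1.0)
    assert tr.stenosis_percent == pytest.approx(50.0)
    # the stenosis formula always holds against the stored diameters
    assert tr.stenosis_percent == pytest.approx(
        (tr.reference_mm - tr.lesion_mm) / tr.reference_mm * 100.0, abs=1e-9
    )


def test_zero_severity_is_identity_profile():
    tree = straight_tree(canvas=192, diameter_mm=2.4, taper=0.01)
    case = generate_phantom(tree, StenosisSpec(14.0, 0.0, 6.0), DegradationSpec(), seed=1)
    tr = case.truth_record
    assert tr.lesion_mm == pytest.approx(tr.reference_mm)
    assert tr.stenosis_percent == pytest.approx(0.0)


def test_resolution_warning_for_subpixel_lumen():
    tree = straight_tree(canvas=192, diameter_mm=2.0, taper=0.0)
    case = generate_phantom(tree, StenosisSpec(14.0, 0.9, 6.0), DegradationSpec(), seed=1)
    assert case.resolution_warning  # lesion 0.2 mm = 1 px < 2 px


def test_invalid_geometry_raises():
    tree = straight_tree(canvas=192)
    with pytest.raises(InvalidSpecError):
        build_geometry(tree, StenosisSpec(arc_position=0.5, severity=0.6, length=6.0))
    with pytest.raises(InvalidSpecError):
        StenosisSpec(arc_position=10.0, severity=1.5, length=6.0)
    with pytest.raises(InvalidSpecError):
        VesselTreeSpec(canvas_size=(32, 32), main_centerline=((1, 1), (20, 20)))


# ------------------------------------------------------------- QCA reference
def test_markers_perpendicular_to_straight_horizontal_vessel(straight_phantom):
    for role in ("proximal_border", "lesion", "distal_border"):
        m = straight_phantom.qca_reference.marker(role)
        # vessel runs along columns -> markers are vertical (constant col)
        assert m.p0[1] == pytest.approx(m.p1[1], abs=1e-6)


def test_reference_diameter_and_lesion_chord_analytic():
    """Untapered 2.5 mm vessel with 60% stenosis: reference diameter is
    2.5 mm and the lesion-marker chord over the truth raster is ~1.0 mm
    (oracle: counting in-class crossing samples along the marker)."""
    tree = straight_tree(canvas=192, diameter_mm=2.5, taper=0.0)
    st = StenosisSpec(14.0, 0.6, 6.0)
    case = generate_phantom(tree, st, DegradationSpec(), seed=0)
    ref = case.qca_reference
    assert ref.reference_diameter == pytest.approx(2.5)
    m = ref.marker("lesion")
    p0, p1 = np.asarray(m.p0), np.asarray(m.p1)
    ts = np.linspace(0, 1, 2001)
    pts = p0 + ts[:, None] * (p1 - p0)
    nearest = case.truth_mask.labels[
        np.rint(pts[:, 0]).astype(int), np.rint(pts[:, 1]).astype(int)
    ]
    chord_px = np.count_nonzero(nearest == CORONARY) * np.linalg.norm(p1 - p0) / 2000
    assert chord_px * tree.pixel_spacing == pytest.approx(1.0, abs=0.25)


def test_qca_reference_requires_stenosis(straight_phantom):
    tree = straight_tree()
    st = StenosisSpec(14.0, 0.0, 6.0)
    geo = build_geometry(tree, st)
    with pytest.raises(InvalidSpecError):
        make_qca_reference(geo, tree, st)


# -------------------------------------------------------------- degradation
def test_zero_degradation_is_identity(random_phantom):
    out = degrade(random_phantom.truth_mask, DegradationSpec(), random_phantom.geometry)
    assert np.array_equal(out.labels, random_phantom.truth_mask.labels)


def test_collateral_gap_removes_one_distal_run():
    rng = np.random.default_rng(5)
    tree, st = sample_tree_and_stenosis(rng, canvas_size=(384, 384), n_branches_range=(1, 1))
    assert len(tree.branches) == 1
    case = generate_phantom(tree, st, DegradationSpec(), seed=5)
    spec = DegradationSpec(collateral_gap_rate=1.0, collateral_gap_length=1.5, seed=5)
    out = degrade(case.truth_mask, spec, case.geometry)
    removed = (case.truth_mask.labels == CORONARY) & (out.labels != CORONARY)
    n_removed = int(removed.sum())
    assert n_removed > 0
    # the gap is confined to the branch: main-tube pixels are untouched
    main = case.geometry.main_tube_mask(case.truth_mask.shape)
    assert not (removed & main).any()
    # roughly one run of the configured length x local branch width
    branch = case.geometry.branches[0]
    width_px = 2 * float(branch.radii_px.mean())
    expected = (spec.collateral_gap_length / tree.pixel_spacing) * width_px
    assert n_removed < 4 * expected


def test_catheter_gap_and_blobs():
    rng = np.random.default_rng(9)
    tree, st = sample_tree_and_stenosis(rng, canvas_size=(256, 256))
    case = generate_phantom(tree, st, DegradationSpec(), seed=9)
    out = degrade(case.truth_mask, DegradationSpec(catheter_gap_rate=1.0, seed=9),
                  case.geometry)
    lost_cath = int(((case.truth_mask.labels == CATHETER) & (out.labels == BACKGROUND)).sum())
    assert lost_cath > 0
    out2 = degrade(case.truth_mask, DegradationSpec(fp_blob_rate=3.0, seed=9), case.geometry)
    fp = (out2.labels == CORONARY) & (case.truth_mask.labels == BACKGROUND)
    assert fp.sum() > 0


def test_dice_monotonically_degrades_with_jitter():
    """Averaged over seeds, realized Dice is non-increasing in sigma."""
    sigmas = [0.4, 1.0, 2.0, 4.0]
    means = []
    for sigma in sigmas:
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            tree, st = sample_tree_and_stenosis(rng, canvas_size=(192, 192))
            case = generate_phantom(tree, st, DegradationSpec(), seed=seed)
            pred = degrade(case.truth_mask, DegradationSpec(boundary_jitter_sigma=sigma, seed=seed))
            vals.append(dice_coefficient(case.truth_mask, pred))
        means.append(np.mean(vals))
    assert all(a >= b for a, b in zip(means, means[1:]))


# -------------------------------------------------------------- calibration
def test_calibrate_identity_target(random_phantom):
    res = calibrate_to_dice(random_phantom.truth_mask, 1.0, seed=1)
    assert res.spec.is_identity
    assert res.realized_dice == 1.0


def test_calibrate_out_of_domain(random_phantom):
    with pytest.raises(DomainError):
        calibrate_to_dice(random_phantom.truth_mask, 0.4, seed=1)


def test_calibrate_unreachable_target_reports_best(random_phantom):
    template = DegradationSpec(collateral_gap_rate=1.0, fp_blob_rate=3.0)
    with pytest.raises(ConvergenceError) as exc:
        calibrate_to_dice(random_phantom.truth_mask, 1.0, seed=1,
                          template=template, geometry=random_phantom.geometry)
    assert exc.value.best_value is not None and exc.value.best_value < 1.0


def test_calibrate_hits_target(random_phantom):
    res = calibrate_to_dice(random_phantom.truth_mask, 0.95, seed=7)
    assert abs(res.realized_dice - 0.95) <= 0.02
    check = dice_coefficient(
        random_phantom.truth_mask,
        degrade(random_phantom.truth_mask, res.spec, random_phantom.geometry),
    )
    assert check == pytest.approx(res.realized_dice, abs=1e-12)


# ----------------------------------------------------------- spec validation
def test_branch_and_catheter_spec_invariants():
    with pytest.raises(InvalidSpecError):
        BranchSpec(attach_arc_mm=5.0, diameter_fraction=1.2, control_points=((0, 0), (5, 5)))
    from angioqca.phantom import CatheterSpec
    with pytest.raises(InvalidSpecError):
        CatheterSpec(french_size=7, control_points=((0, 0), (5, 5)))
    with pytest.raises(InvalidSpecError):
        DegradationSpec(collateral_gap_rate=1.5)
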