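"""Controlled degradation of truth masks into "model prediction" masks.

The defect taxonomy mirrors what segmentation models actually get wrong on
coronary angiograms: a small systematic over/under-segmentation of the
vessel caliber, random boundary jitter, gaps in the distal parts of small
collateral branches, a gap in the catheter near its tip (where contrast
backflow obscures it), and the occasional false-positive blob away from the
vessel.

Bias and jitter are applied jointly through a signed-distance threshold:
``new = (sEDT + diameter_bias/2 + noise) > 0`` where the noise is a smooth
Gaussian random field scaled to a pointwise standard deviation of
``boundary_jitter_sigma`` pixels — the level-set shifts by the noise value,
so sigma is calibrated directly in pixels of boundary displacement.

Every defect type draws from its own child RNG stream of the root seed, so
toggling one defect never changes the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConvergenceError, DomainError, InvalidSpecError
from .geometry import PhantomGeometry, stamp_tube
from .masks import BACKGROUND, CATHETER, CORONARY, SegmentationMask
from .overlap import dice_coefficient

#: correlation length (px) of the boundary-jitter noise field
JITTER_CORRELATION_PX = 2.0


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the synthetic defect model.

    Rates are probabilities (or expected counts, for blobs); lengths are in
    mm; sigma and bias are in pixels.
    """

    boundary_jitter_sigma: float = 0.0
    diameter_bias: float = 0.0
    collateral_gap_rate: float = 0.0
    collateral_gap_length: float = 1.5
    catheter_gap_rate: float = 0.0
    catheter_gap_length: float = 2.0
    fp_blob_rate: float = 0.0
    fp_blob_diameter: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("collateral_gap_rate", "catheter_gap_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if self.fp_blob_rate < 0:
            raise InvalidSpecError("fp_blob_rate must be >= 0")
        if self.boundary_jitter_sigma < 0:
            raise InvalidSpecError("boundary_jitter_sigma must be >= 0")
        for name in ("collateral_gap_length", "catheter_gap_length", "fp_blob_diameter"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.boundary_jitter_sigma == 0
            and self.diameter_bias == 0
            and self.collateral_gap_rate == 0
            and self.catheter_gap_rate == 0
            and self.fp_blob_rate == 0
        )


def _jittered(mask_bool: np.ndarray, bias_px: float, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Threshold the signed distance field plus bias and smooth noise."""
    if not mask_bool.any():
        return mask_bool.copy()
    sdist = ndimage.distance_transform_edt(mask_bool) - ndimage.distance_transform_edt(~mask_bool)
    field = sdist + bias_px / 2.0
    if sigma_px > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(mask_bool.shape), JITTER_CORRELATION_PX)
        std = noise.std()
        if std > 0:
            field = field + noise * (sigma_px / std)
    return field > 0


def _arc_gap_removal(
    shape: tuple[int, int],
    tube,
    s_start_px: float,
    s_stop_px: float,
    extra_radius_px: float,
) -> np.ndarray:
    """Boolean removal stencil: disks along an arc interval of a tube."""
    cl = tube.centerline
    i0 = max(int(np.floor(s_start_px / cl.step_px)), 0)
    i1 = min(int(np.ceil(s_stop_px / cl.step_px)) + 1, cl.n)
    field = np.full(shape, -np.inf)
    radii = np.asarray(tube.radii_px, float) + extra_radius_px
    stamp_tube(field, cl, radii, start=i0, stop=i1)
    return field >= 0


def degrade(
    truth: SegmentationMask,
    spec: DegradationSpec,
    geometry: PhantomGeometry | None = None,
) -> SegmentationMask:
    """Apply the defect model to a truth mask.

    ``geometry`` supplies the arc-length parametrisation needed to place
    collateral and catheter-tip gaps; without it, only bias, jitter and
    false-positive blobs are applied (a bare mask does not carry branch
    topology).  An all-zero spec returns an identical mask.
    """
    if spec.is_identity:
        return truth.copy()

    ss = np.random.SeedSequence(spec.seed)
    rng_jitter, rng_branch, rng_cath, rng_blob = (np.random.default_rng(c) for c in ss.spawn(4))

    spacing = truth.pixel_spacing
    cor = truth.class_mask(CORONARY)
    cat = truth.class_mask(CATHETER)

    # 1-2. signed diameter bias + boundary jitter (coronary); jitter only (catheter)
    if spec.boundary_jitter_sigma > 0 or spec.diameter_bias != 0:
        cor = _jittered(cor, spec.diameter_bias, spec.boundary_jitter_sigma, rng_jitter)
        cat = _jittered(cat, 0.0, spec.boundary_jitter_sigma, rng_jitter)

    margin = spec.boundary_jitter_sigma * 2.0 + abs(spec.diameter_bias) + 2.0

    # 3. collateral gaps: one zeroed run per Bernoulli hit, in the distal half
    if geometry is not None and spec.collateral_gap_rate > 0 and geometry.branches:
        main_tube = geometry.main_tube_mask(truth.shape)
        for branch in geometry.branches:
            if rng_branch.random() >= spec.collateral_gap_rate:
                continue
            length_px = branch.centerline.length_px
            gap_px = spec.collateral_gap_length / spacing
            lo = 0.5 * length_px
            hi = max(length_px - gap_px, lo)
            start = lo if hi == lo else rng_branch.uniform(lo, hi)
            removal = _arc_gap_removal(truth.shape, branch, start, start + gap_px, margin)
            cor &= ~(removal & ~main_tube)

    # 4. catheter gap near the tip (contrast backflow)
    if (
        geometry is not None
        and geometry.catheter is not None
        and spec.catheter_gap_rate > 0
        and rng_cath.random() < spec.catheter_gap_rate
    ):
        tube = geometry.catheter
        gap_px = spec.catheter_gap_length / spacing
        removal = _arc_gap_removal(
            truth.shape, tube, tube.centerline.length_px - gap_px, tube.centerline.length_px, margin
        )
        cat &= ~removal

    # 5. false-positive blobs: disks placed off-vessel
    if spec.fp_blob_rate > 0:
        n_blobs = int(rng_blob.poisson(spec.fp_blob_rate))
        if n_blobs > 0:
            radius = spec.fp_blob_diameter / 2.0
            foreground = cor | cat | truth.class_mask(CORONARY) | truth.class_mask(CATHETER)
            dist_to_fg = ndimage.distance_transform_edt(~foreground)
            rows, cols = truth.shape
            placed = 0
            attempts = 0
            rr = cc = None
            while placed < n_blobs and attempts < 50 * n_blobs:
                attempts += 1
                r = rng_blob.uniform(radius + 1, rows - radius - 2)
                c = rng_blob.uniform(radius + 1, cols - radius - 2)
                if dist_to_fg[int(round(r)), int(round(c))] < radius + 3:
                    continue
                rr = np.arange(rows, dtype=float)[:, None]
                cc = np.arange(cols, dtype=float)[None, :]
                cor |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
                placed += 1

    labels = np.full(truth.shape, BACKGROUND, dtype=np.uint8)
    labels[cat] = CATHETER
    labels[cor] = CORONARY  # coronary class wins where tubes touch
    return SegmentationMask(labels, spacing)


@dataclass(frozen=True)
class CalibrationResult:
    spec: DegradationSpec
    realized_dice: float


def calibrate_to_dice(
    truth: SegmentationMask,
    target_dice: float,
    seed: int,
    template: DegradationSpec | None = None,
    geometry: PhantomGeometry | None = None,
    tolerance: float = 0.02,
    max_iter: int = 30,
) -> CalibrationResult:
    """Bisect ``boundary_jitter_sigma`` until the whole-image coronary Dice
    of the degraded mask is within ``tolerance`` of ``target_dice``.

    All other defect parameters come from ``template`` (default: no other
    defects).  Raises :class:`ConvergenceError`, naming the best realized
    value, when the target is unreachable (e.g. 1.0 with mandatory gaps).
    """
    if not 0.5 < target_dice <= 1.0:
        raise DomainError("target_dice must lie in (0.5, 1.0]")
    template = template if template is not None else DegradationSpec()

    def realized(sigma: float) -> float:
        spec = replace(template, boundary_jitter_sigma=sigma, seed=seed)
        if spec.is_identity:
            return 1.0
        pred = degrade(truth, spec, geometry)
        return dice_coefficient(truth, pred, CORONARY)

    lo, d_lo = 0.0, realized(0.0)
    if d_lo < target_dice - tolerance:
        raise ConvergenceError(
            f"target Dice {target_dice} unreachable: best realized {d_lo:.4f} at sigma 0",
            best_value=d_lo,
        )
    if abs(d_lo - target_dice) <= tolerance and (
        target_dice == 1.0 or d_lo - target_dice <= tolerance / 2
    ):
        spec = replace(template, boundary_jitter_sigma=0.0, seed=seed)
        return CalibrationResult(spec, d_lo)

    hi, d_hi = 1.0, realized(1.0)
    grow = 0
    while d_hi > target_dice and grow < 8:
        hi *= 2.0
        d_hi = realized(hi)
        grow += 1
    if d_hi > target_dice:
        raise ConvergenceError(
            f"could not bracket target Dice {target_dice}: Dice {d_hi:.4f} at sigma {hi}",
            best_value=d_hi,
        )

    best_sigma, best_dice = (lo, d_lo) if abs(d_lo - target_dice) < abs(d_hi - target_dice) else (hi, d_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = realized(mid)
        if abs(d_mid - target_dice) < abs(best_dice - target_dice):
            best_sigma, best_dice = mid, d_mid
        if abs(d_mid - target_dice) <= tolerance / 2:
            break
        if d_mid > target_dice:
            lo = mid
        else:
            hi = mid
    if abs(best_dice - target_dice) > tolerance:
        raise ConvergenceError(
            f"calibration did not converge: best Dice {best_dice:.4f} for target {target_dice}",
            best_value=best_dice,
        )
    return CalibrationResult(
        replace(template, boundary_jitter_sigma=best_sigma, seed=seed), best_dice
    )
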