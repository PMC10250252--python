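# Methods

This note documents the models, conventions and numerical choices behind
`angioqca`: what the synthetic phantoms emulate, how the caliper measures a
binary mask, how degradation is calibrated, and what the statistics assume.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and class conventions

All grids are 0-based `(row, col)` with pixel centers at integer
coordinates; a pixel belongs to a class when its center lies inside the
analytic shape. Classes are `0` background, `1` coronary, `2` catheter;
masks persist as 8-bit grayscale PNG with values 0/255/128. Pixel spacing
is isotropic (mm/px); anisotropic spacing is rejected at load. Where the
catheter tip meets the vessel origin the coronary class wins.

## Phantom model

A phantom vessel is a tube around a smooth centerline with diameter profile

    d(s) = d0 · (1 − τ·s) · n(s)

where `s` is arc length in mm, `d0` the baseline diameter at the origin,
`τ` the taper rate (fraction of diameter lost per mm), and `n(s)` a
raised-cosine stenosis notch

    n(s) = 1 − sev · cos²(π (s − s0) / L)   for |s − s0| ≤ L/2,  else 1,

reaching `1 − sev` at the lesion center `s0` over length `L`. The smooth
profile avoids rasterization artifacts exactly at the marker positions; no
claim is made that real lesions have this shape. Truth records (border
diameters, lesion diameter, reference diameter = healthy profile at `s0`,
percent stenosis) are evaluated from this formula, never from pixels, so
truth stenosis equals `sev × 100` exactly.

Centerlines are parametric cubic splines through control points, resampled
to a uniform 0.25 px arc step. Rasterization stamps a disk of the local
radius at every sample and thresholds the resulting max-field at zero
(pixel-center-inside rule); at this step size the union-of-disks
approximation error is far below one pixel.

The random case sampler emulates one projected diseased coronary segment:

* canvas 512×512 at 0.2 mm/px (a typical angiographic zoom);
* main vessel crossing the canvas obliquely (base angle 20–70° from the
  image axes) with a large-scale sinusoidal sweep plus a 1.5–3 px
  high-frequency tremor — projected coronaries are tortuous at several
  scales, and a perfectly straight, grid-aligned tube is both unrealistic
  and pathological for any digital width measurement (width information
  quantizes to ~0.7–1 px steps when an edge is locked to the grid at 0°,
  45° or 90°);
* baseline diameter 2.4–3.6 mm, taper 0.003–0.007 per mm;
* one to three collateral branches (35–65° take-off, 0.35–0.6 of the local
  main diameter), with roots kept ≥ 8 mm away from the lesion window so a
  branch never lies under a measurement marker — a configuration that would
  also defeat a real QCA analysis;
* a 5 or 6 Fr catheter entering from the nearest canvas edge to the vessel
  origin;
* one focal stenosis at 30–60% of the vessel arc, length 5–8 mm, severity
  drawn from configurable strata (defaults 35% at 0.30–0.50, 47% at
  0.50–0.70, 18% at 0.70–0.95 — the measured-severity mix of a visually
  selected 50–99% stenosis cohort).

Geometrically invalid draws are retried; the draw is deterministic per case
seed.

What the phantoms do **not** emulate: grayscale X-ray appearance, vessel
overlap/foreshortening, motion, anisotropic spacing, and real lesion
morphology (eccentricity, calcium). Passing tests therefore validate the
*measurement layer* — caliper, overlap, statistics, bookkeeping — not any
segmentation model, and transfer to real data only insofar as the
measurement procedure is the same.

## QCA reference records

Each case carries a reference record in the layout a QCA workstation
exports: three marker lines perpendicular to the centerline at the proximal
border, lesion center and distal border (half-length 1.5× the local healthy
diameter, so the chord search cannot truncate; an error is raised if a
marker would leave the canvas), the reference diameter, the mm/px
calibration, and two catheter caliper lines. The caliper lines are the
catheter *edge* lines — parallel to the catheter axis, one on each side, so
their perpendicular separation is the catheter diameter. On reference data
the catheter measurement is that separation times calibration; on a
segmented mask it is the catheter-class chord along a probe perpendicular
to and midway between the two lines. Marker orientation
(perpendicular-to-centerline) is an assumption; reference systems do not
document theirs.

## Caliper measurement

`chord_length` samples a marker line every 0.1 px; a sample is in-class
when its nearest pixel carries the class; the chord is the contiguous
in-class run containing the sample nearest the line midpoint. If the
midpoint sample is out-of-class the nearest run within 2 px is used
(markers sit on the reference image and may be slightly off-center on the
prediction); otherwise a *gap* is signalled. Gaps mark the case excluded —
mirroring how gap cases are dropped from a validation study — and excluded
cases never reach the statistics (enforced by the audit). The
contiguous-run rule deliberately refuses to sum disjoint runs, which would
silently overestimate diameters across gaps.

A single digital chord is quantized to roughly ±1 px, which at a 10 px
reference width is ±10 stenosis points — useless near the resolution
limit. `measure_markers` therefore refines each diameter with sub-pixel
edge localization standard in QCA practice: chords are measured on a fan of
33 lines parallel to the marker, offset ±8 px along the local vessel
direction, and a quartic polynomial fit of chord versus offset is evaluated
at offset zero. Averaging across the raster staircase removes most of the
quantization; the polynomial absorbs the genuine diameter variation around
a stenosis (the raised-cosine waist is locally even in the offset) so the
fit does not bias the minimum-lumen value; the fitted value is clipped to
the observed chord range to guard ill-conditioned fits. Gap status is
always decided by the central line alone under the nearest-pixel rule. The
sampling step bounds residual discretization error at ~0.02 px·mm scales,
well below the smallest differences the statistics summarize.

Percent stenosis uses the reference diameter from the reference record; a
lesion chord larger than the reference yields a negative value that is
reported and flagged, never clamped — clamping would bias the paired
statistics.

## Degradation model

`DegradationSpec` controls five defect families applied in order; every
family draws from its own child stream of the root seed, so toggling one
defect never changes the others' draws. An all-zero spec is the identity.

* **Caliber bias + boundary jitter** (coronary class; jitter only for the
  catheter): the mask is re-thresholded as
  `signed-EDT + bias/2 + noise > 0`, where the noise is white Gaussian
  smoothed with a 2 px kernel and rescaled to pointwise standard deviation
  `sigma`. Because the level set shifts by the noise value, `sigma` is
  calibrated directly in pixels of boundary displacement, and `bias` (in px
  of diameter, signed) supports sub-pixel systematic over/under-segmentation.
* **Collateral gaps**: per branch, with probability `collateral_gap_rate`,
  a run of the configured length is removed from the distal half of the
  branch (where such gaps occur in practice), without eroding main-vessel
  pixels.
* **Catheter-tip gap**: with probability `catheter_gap_rate`, the catheter
  is erased over the configured length adjacent to its tip — the region
  contrast backflow obscures.
* **False-positive blobs**: a Poisson number of disks placed at least 3 px
  clear of any foreground.

The default study template uses sigma calibrated at run time, −0.5 px
caliber bias, 35% collateral-gap rate (1.5 mm), 25% catheter-gap rate
(2 mm), and one expected 4 px blob per image — a defect mix chosen to
reflect the qualitative defect profile reported for coronary segmentation
models (frequent mild distal collateral gaps, common catheter-tip defects,
slight caliber underestimation).

`calibrate_to_dice` bisects `boundary_jitter_sigma` (all other defects from
the template) until the whole-image coronary Dice of the degraded mask is
within 0.02 of the target, at most 30 iterations; an unreachable target
(e.g. 1.0 with mandatory gaps) raises a convergence error naming the best
realized value. The study pipeline calibrates on a few representative cases
(default 3) and applies the pooled sigma study-wide; per-case Dice then
scatters around the target with the geometry.

## Overlap

Counts are computed on the coronary class by default (per-class computation
is available), within either the marker-bounding-box ROI (default padding
10 px) or the whole image — the exact ROI used by reference analyses is not
documented, so both modes are first-class and the ROI is reported. A metric
with a zero denominator is *undefined*: reported as NaN with a warning,
propagated as missing — never as zero. Dice and IoU satisfy
`D = 2J/(1+J)` per case; the audit asserts it numerically at 1e−9.

## GSS

The rubric schema enforces criteria summing to exactly 100 with unique ids.
The shipped default rubric (main-vessel completeness 40, collateral
continuity 20, catheter continuity 20, artifact burden 20) is explicitly
illustrative — the canonical criteria and weights live with the rubric's
authors — and is fully replaceable via configuration. Consensus is stored
as a single assessment row, not derived from rater rows. Aggregation:
median and IQR of totals over fully scorable images; images whose catheter
cannot be scored (collimation) are excluded from totals and catheter
criteria but still contribute to other per-criterion medians. Quantiles use
linear interpolation between order statistics, consistently with the
statistics module.

## Statistics

Normality is checked with Shapiro–Wilk at α = 0.05 (the test choice is a
documented decision; a constant vector is reported degenerate-non-normal
without crashing). Paired arms use the paired t-test when the differences
pass, Wilcoxon signed-rank otherwise; all-zero differences short-circuit to
p = 1 with a degeneracy flag. Independent groups use Mann–Whitney U (2
groups) or Kruskal–Wallis (> 2). Difference columns are summarized as the
median (25th–75th) of **absolute** per-case differences — which is why the
reported IQRs start at or near zero. Significance is p < 0.05 with no
multiple-testing correction. Both conventions (absolute differences;
non-normal fallback) are decisions where reference reporting is ambiguous,
and are stated here rather than guessed silently.

## Study pipeline

The "original" arm of every paired comparison defaults to the analytic
truth record — the stand-in for the reference QCA export — so that the
measurement error of the method under test is not confounded with phantom
rasterization error; caliper-on-truth is recorded per case as a consistency
column and can be made the original arm (`original_arm="caliper_truth"`)
for pure pixel-identity checks. Any per-case failure is recorded with its
reason and excluded, never aborting the study. The audit verifies:
generated = included + excluded with per-reason counts, every excluded case
carries a reason, statistics used exactly the included cases, and the
per-case Dice–IoU identity. Reports contain no timestamps, so identical
configs and seeds produce hash-identical files.

Default problem sizes — 120–123 cases at 512×512, three calibration cases,
100-phantom recovery sweeps, 1000-replicate null simulations — keep a full
study plus its verification suite within a couple of minutes on one CPU
while leaving quantile and rate estimates stable to well under their
asserted tolerances.

## Known limitations

* Width information in a binary mask is fundamentally quantized when a
  locally straight edge aligns with the pixel grid at 0°, 45° or 90°; the
  caliper's fan refinement needs some local obliquity or curvature (real
  vessels provide it, and the phantom sampler guarantees it).
* Severity ≥ 0.9 at typical spacing puts the lumen below ~2 px; such cases
  carry a resolution warning and, under degradation, are the ones that gap
  and get excluded — as in real studies.
* The GSS layer aggregates human scores; it does not predict them.
* Catheter measurements assume the caliper lines bracket a locally straight
  catheter segment away from the tip.
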