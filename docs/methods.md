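# Methods

This note documents the models, conventions, and numerical choices
behind `ductiometry`, and what the synthetic-data tests do and do not
establish about real recordings.

## Coordinate conventions

All geometry lives in one right-handed, viewer-fixed frame: x =
rightward, y = upward, z = out of the image toward the camera. Angles
are degrees, counterclockwise from +x, reported in [0°, 360°). Input
files in image-row convention (y down) are flipped on load
(`read_boundaries(..., y_down=True)`).

Ductions carry the eight viewer-fixed gaze labels (`right`, `up_right`,
…, `down_right`) rather than anatomical names; mapping "adduction of
the right eye" to "leftward" happens at the labeling layer
(`directions.MIRROR_LABEL` pairs mirror gazes), so the math never
branches on eye.

## Eye model and forward projection

The globe rotates rigidly about a fixed center of rotation. The limbus
is a planar ring 10.45 mm in front of that center (corneal apex at
12.95 mm minus a 2.5 mm corneal sagittal depth; these satisfy the
additive identity exactly and are validated at construction). The
center of rotation is assumed not to translate during movements —
modeling its translation would add participant-specific free parameters
with no data to constrain them.

Pixel coordinates are calibrated per participant: mm/px = 11.75 mm
(population-average horizontal visible iris diameter) divided by the
horizontal pixel width of that participant's fitted primary-gaze
ellipse. Head translations measured externally (e.g., by registering a
facial marker) are corrected by shifting all boundary points opposite
the displacement; head *rotations* are not correctable this way.

The projection is orthographic (drop z). A single global mm/px factor
is only consistent with a parallel projection, and at a 40 cm viewing
distance the perspective error across a 12 mm iris is second order.
Consequently the fitted primary-gaze ellipse is taken to *be* the
orthographic image of the limbus: its shape, re-centered on the optical
axis, is embedded as a planar 3D ring at z = 10.45 mm. This makes the
zero-rotation forward projection reproduce the fitted 2D ring exactly
(self-consistency), at the cost of ignoring any true tilt of the limbus
plane in primary gaze — the degenerate (untilted) reading of an
ambiguity the protocol itself does not resolve.

Rotation axes are confined to Listing's plane (zero z component, i.e.,
no torsion). Rotations use the axis–angle (Rodrigues) map via
`scipy.spatial.transform.Rotation`; the axis `[p1, p2, 0]` is
normalized to unit length before use because only its direction is
meaningful — `p1` and `p2` are the components about which vertical and
horizontal displacements of gaze occur, respectively.

Ellipse fitting is the direct least-squares conic fit with ellipse
constraint (`skimage.measure.EllipseModel`), all points weighted
equally; the RMS point-to-ellipse distance is reported as a fit
diagnostic. Segmentation masks produced by external tools can be scored
with `mask_metrics` (accuracy, sensitivity, specificity, precision from
the pixel confusion matrix); ratios with empty denominators are
returned as `None`, never silently 0.

## Rotation estimation

`estimate_rotation` inverts the forward map with a Nelder–Mead simplex
search over `(p1, p2, θ)`:

* **Objective.** The rotated, projected reference ring and the observed
  boundary (expressed relative to the fitted reference center) are both
  resampled at `n_samples = 360` equally spaced polar angles about the
  *observed* ring's centroid; the error is the sum over samples of
  same-angle distances (so a mean correspondence distance is the
  reported error divided by 360). Polar resampling interpolates radius
  against angle with periodic boundary; a ring that does not wind
  exactly once about the center (figure-eight, center outside) raises a
  diagnostic error, which the objective converts to a large penalty.
* **Bounds.** `p1, p2 ∈ [−1, 1]`, `θ ∈ [0°, 90°]`, enforced by clamping
  inside the objective plus a penalty proportional to the violation;
  returned parameters are clamped.
* **Initialization.** θ₀ from the chord formula `θ₀ = 2·asin(c/2r)`
  applied to the projected centroid displacement `c` at ring-center
  radius `r`; initial axis perpendicular to the displacement (the axis
  that moves gaze along it). Four jittered restarts (axis ±20° SD,
  θ ±5° SD, seeded) guard against local minima; the best minimum is
  kept, with `converged=False` flagging best-so-far results at the
  iteration cap.
* **Accuracy.** On noiseless forward simulations over
  θ ∈ {5°,…,60°} × 8 directions, magnitudes are recovered to ≪ 0.5° and
  directions to ≪ 2°; with 0.05 mm boundary noise the estimate sits
  within ~0.1° of an exhaustive 1° grid search.

Per duction and eye, the `k = 3` least-error frames (of 5) are retained
(`select_least_error`), ties broken by frame index for reproducibility;
selection runs within each duction so all eight stay represented. A
rotation estimate becomes a duction vector with magnitude θ and
direction equal to the polar angle of the projected displacement of the
ring center — for an axis `(a₁, a₂, 0)` this is `atan2(−a₁, a₂)`. θ = 0
has no defined direction and maps to the null vector.

## Summary indices

Duction tips are connected in order of direction angle, which yields a
simple polygon for any magnitudes; areas use `shapely`. Motor-field
normalization divides by the cohort mean *per eye* (OD areas by the
mean of OD areas), so the normalized values average to exactly 1 per
eye; single-participant use can pass externally supplied normative
means. Discrepancies divide the symmetric-difference area by the sum of
both polygon areas using raw deg² areas (units cancel), after
reflecting the OS polygon about the vertical axis for the motor kind.

Dipoles: `sign(0)` is defined as +1 so zero components never flip
orientation; when the two eyes are identical the max-norm normalizer of
the difference dipoles is 0 and the exact zero dipole is returned (the
well-defined limit). Zero-magnitude dipoles carry a null direction.

One structural property deserves emphasis. The difference dipoles are
*scale-free*: difference vectors are normalized by the largest
difference magnitude before averaging. In a cohort whose anisotropy is
mirror-symmetric between the eyes (the normative situation: each eye
adducts ~8° further than it abducts), the systematic gaze differences
on opposite labels are equal in size and — because each difference
vector is signed by the right eye's components — point in opposite
directions, cancelling in the vector average while still inflating the
normalizer. The *normalized* gaze-difference magnitude is therefore
systematically smaller than the muscle-difference magnitude on
mirror-symmetric cohorts, even though the *raw* interocular differences
between matching gazes dwarf those between matching ductions. For this
reason each difference dipole also reports `mean_raw_norm`, the mean
un-normalized difference magnitude in degrees, and the
"matching ductions are more alike than matching gazes" benchmark is
asserted on that raw scale.

## Measurement error and change detection

`SEm = √(SSE/df)` from a repeated-measures ANOVA on an N×2 matrix. The
default model is the balanced two-way additive decomposition
(participant + occasion effects, `df = (N−1)(k−1)`), computed in closed
form (`x_ij − x̄_i· − x̄_·j + x̄..`); `statsmodels` OLS reproduces it
exactly and serves as the independent oracle in the tests. A
participant-only model (`model="one_way"`, `df = N(k−1)`; for k = 2
equivalently `Σd_i²/2N`) is available since the exact ANOVA structure
used for SEm derivations varies across the literature.

`MDC95 = 1.96·SEm·√2`: 1.96 sets the 95% confidence level and √2
accounts for the difference of two noisy measurements. Resampling draws
two replicates per participant (without replacement) from their pool —
for ductions, the 3 selected estimates; for indices, index values
recomputed from randomly drawn per-duction estimates, with motor fields
re-normalized within each drawn cohort — computes one MDC95 per
iteration, and repeats 1,000 times by default under a single seed.
Participants with fewer than two replicates are excluded with a
warning, not imputed. Direction metrics are resampled on the wrapped
offset from each duction's nominal meridian, and `flag_change(...,
circular=True)` wraps longitudinal direction changes to the minimal arc
(a `circular=False` path reproduces raw-difference conventions).

## Synthetic data

The simulator emulates the normative recording design: 20 participants;
per participant 82 frames (one primary-gaze frame per eye plus 5
fixation frames per duction per eye), distilled to the 3 least-error
frames per duction. Defaults, chosen once from normative ranges:

| parameter | default | rationale |
|---|---|---|
| duction mean profile | adduction 46.6°, adducted-depression 42.4°, elevation 31.3°, others 35–42° | midpoints of reported normative CIs; grand mean ≈ 39° |
| between-subject SD | 4° | CI half-widths at N = 20 |
| within-subject SD | 1.6° | back-derived from the 4–8° duction-magnitude MDC band via σ = MDC/(1.96√2) |
| direction jitter SD | 4° | fixation scatter about the rope meridians |
| interocular asymmetry SD | 1° | small residual mirror asymmetry |
| boundary noise SD | 0.05 mm | segmentation pixel noise at 0.10 mm/px |
| occlusion fraction | ≤ 0.2 of the ring arc | lid coverage; rings more than half obscured are excluded by design |
| head translation SD | 0.3 mm | reported mean displacements of 0.24/0.31 mm |

The OS profile mirrors the OD profile about the vertical axis plus the
asymmetry noise. All draws flow from a single config seed
(bit-reproducible), and ground truth (axis, angle, displacement) is
always emitted alongside the simulated frames.

What the generator does **not** emulate: real segmentation error
structure (correlated, lid-dependent, worst in downgaze), perspective
effects, torsion, center-of-rotation translation, participant fatigue
or learning across fixations, and any demographic structure. Passing
tests therefore establish that the *pipeline* is correct and
well-conditioned under realistic noise magnitudes, not that the
specific normative values would be reproduced in a new human cohort.

## Problem sizes and numerical choices

The test suite and acceptance script keep simulations at the smallest
sizes that exercise the design: full 20-participant cohorts at the
vector level (cheap), 1–2 participants through the full
boundary-estimation pipeline, 100–200 MDC iterations per metric in
pipeline runs (the standalone `resample_mdc` default remains 1,000),
and a σ-recovery check that spreads 1,000 iterations over 10
independent cohorts so the recovered value reflects the generating σ
rather than one finite cohort draw. Embedded rings use 180–360 points;
correspondence errors use 360 polar samples (1° steps). Floating-point
tolerances: geometric identities at 1e-9, statistical recoveries at
5–10% relative.

## Known limitations

* The correspondence error assumes both rings are star-shaped about the
  observed centroid; extreme occlusions (> half the ring) or grossly
  non-elliptical segmentations are rejected rather than estimated.
* Direction MDCs inherit a 0°/360° wrap ambiguity when a participant's
  replicates straddle a meridian; resampling on wrapped offsets
  resolves it for jitter ≪ 180° but not for pathological scatter.
* The tilt of the primary-gaze limbus plane is unidentifiable from a
  single orthographic view; the untilted embedding is a convention.
* Normalized difference dipoles are insensitive to mirror-symmetric
  interocular differences (see above); use `mean_raw_norm` when the
  absolute difference scale matters.
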