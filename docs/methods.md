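# Methods

This note documents the models, conventions and numerical choices behind
`neckssm`, and what the synthetic cohort does and does not emulate.

## Problem and pipeline

The infrarenal aortic neck — the aortic segment between the lowest renal
artery and the start of an abdominal aortic aneurysm — is the proximal
sealing zone of an EVAR endograft. Hostile neck anatomy (short, wide,
angulated, conical) predisposes to late type Ia endoleak. The package
models the neck's full 3D geometry as a point-distribution shape model
and asks whether its mode scores discriminate endoleak cases from
controls better than, or in combination with, conventional workstation
measurements.

Stages: synthetic cohort generation → landmark parametrization → rigid
alignment → PCA shape model → conventional measurements → group
comparisons and logistic discrimination. All stages run on mm-scale
coordinates in patient-like axes (x = left, y = anterior, z = cranial).

## Synthetic cohort generator

No clinical geometry is distributed, so the generator is a first-class,
tested stage that emulates the per-patient inputs: a triangulated lumen
surface, a center lumen line (CLL), the renal and distal-neck-end
markers, 3-level calcification/thrombus labels, and a case/control group
label.

**Tube model.** Each neck is a swept circular tube around a centerline
with five arc-length segments: straight suprarenal trunk, circular-arc
transition bending the tangent by the suprarenal angle, straight tapering
neck (renal marker at its start, distal marker at its end), a second arc
bending by the infrarenal angle, and a flaring sac-entry segment. Both
bends lie in one plane chosen by an azimuth. Cross-sections are circles
whose diameter is constant proximally, grows linearly by the taper
fraction over the neck (default +10%, so the distal marker coincides with
the +10%-diameter detection rule), and flares further into the sac.
Vertex radii get i.i.d. Gaussian noise (default SD 0.2 mm) to emulate
segmentation roughness.

**Bend transitions.** Tangent bends are circular arcs so curvature stays
bounded and tangents well defined. A transition arc whose radius is
smaller than the tube radius would fold the swept surface into itself;
at clinically typical bends (≈50° at ≈26 mm diameter) that rules out
very short transitions. The default arc radius is therefore 1.5× the
local tube radius (transition length = 1.5 · r · θ); an explicitly
shorter transition raises a geometry error.

**Calibration.** Group parameter distributions are fitted to the
published case/control summary statistics (median and quartiles):

| parameter | family | case | control |
|---|---|---|---|
| neck length (mm) | log-normal | median 13.0, σ_log 1.046 | median 26.0, σ_log 0.621 |
| neck diameter (mm) | log-normal | median 26.1, σ_log 0.132 | median 24.3, σ_log 0.084 |
| suprarenal angle (°) | trunc. normal [0, 89) | median 36, scale 25.6 | median 30, scale 17.1 |
| infrarenal angle (°) | trunc. normal [0, 89) | median 52, scale 21.9 | median 47, scale 18.2 |

σ_log = ln(Q3/Q1) / (2 · 0.67449); the truncated-normal location is
solved numerically so the *truncated* median equals the printed median.
Quartiles match exactly in log-symmetric approximation only; tails are
not calibrated (the sources report no tail information). Bend-plane
azimuth is uniform on [0°, 360°).

Calcification/thrombus category probabilities are chosen once to
reproduce the printed per-group category medians and quartiles while
keeping the groups as close as those constraints allow: calcification
case (0.78, 0.12, 0.10) vs control (0.48, 0.28, 0.24); thrombus case
(0.50, 0.25, 0.25) vs control (0.49, 0.25, 0.26). Note a structural
tension: the printed calcification quartiles (case Q3 = 0 vs control
median = 1) force a ≥25-point gap in the "absent" fraction, so the
synthetic cohort's Fisher test on calcification comes out significant at
n = 63 + 63 even though the clinical study reported it non-significant;
thrombus, whose printed quartiles permit near-identical distributions, is
calibrated to be non-significant.

**What the generator does not emulate.** Lumen cross-sections are
circular (real necks are irregular); calcification/thrombus have no
geometric counterpart (they enter only as covariates); and the neck
segment itself is straight — angulation lives in the transitions just
outside the marked neck. A consequence of that last simplification is
that landmark variance is dominated by neck length: the leading PCA mode
of a default synthetic cohort carries ~99% of total variance and the 98%
threshold typically retains a single mode, whereas clinical necks spread
variance over many modes. Passing tests therefore demonstrate the
*machinery* (correspondence, PCA algebra, model comparison) under
controlled conditions, not the clinical variance structure.

**Determinism.** Every random draw descends from one `SeedSequence`;
identical seed and specs give a bitwise-identical cohort.

## Landmark parametrization

- **Distal neck end**: walking distally from the renal baseline in 0.5 mm
  arc-length steps, the first cross-section whose area-equivalent
  diameter reaches 110% of the renal-baseline diameter, refined by linear
  interpolation between the bracketing steps.
- **Diameter** of a contour is always the area-equivalent diameter
  2·sqrt(A/π), with A the shoelace area of the plane-mesh intersection
  polygon. This is rotation-invariant and matches common workstation
  definitions; min/max/mean calliper diameters are not used anywhere.
- **Levels**: 10 points equally spaced in arc length from the renal
  marker to the distal end (inclusive), tangents by central differences
  on the interpolated centerline.
- **Contours**: per level, the closed plane-mesh intersection polyline
  whose centroid is nearest the centerline point (robust to side-branch
  slivers) is resampled along 360 rays from the level point, nearest
  crossing per ray. Azimuth 0 is the projection of the anterior axis
  (+y) onto the cutting plane, increasing counterclockwise viewed from
  cranial; if the tangent is parallel to +y the projection of +x is used
  and a warning logged. Anterior was chosen as the correspondence anchor
  because it is the only anatomically stable reference derivable from
  the inputs.
- **Alignment**: rigid only (translation + rotation, no scaling — size
  is discriminative signal), anchored entirely at the renal baseline:
  level-0 centroid to the origin, level-0 distal tangent to +z, the
  anterior reference landmark direction to +y. Alignment is idempotent.

One caveat on equivariance: the azimuthal anchor is a *global* direction
projected per plane, so rotating a subject changes which anatomical point
is azimuth 0. For the circular-section synthetic subjects this is
invisible (tested); for strongly non-circular lumens, landmark
correspondence across differently oriented scans inherits the anterior
convention of the scan axes.

## Shape model

Standard point-distribution model on the aligned, flattened grids
(d = 10·360·3 = 10 800 coordinates): mean shape plus orthonormal modes
from the eigendecomposition of the sample covariance (divisor n−1). With
n ≪ d at most n−1 modes carry variance. Numerics:

- computed via SVD of the centered data matrix (never the explicit
  10 800² covariance); the covariance eigendecomposition is kept as an
  independent test oracle;
- mode signs fixed so each mode's largest-magnitude loading is positive,
  making scores platform-reproducible;
- variances below max(1e-10 × total, floating-point floor of the data
  scale) count as zero, which makes the all-identical-shapes cohort
  cleanly degenerate (0 retained modes, all scores 0);
- retained modes: smallest leading set reaching 98% cumulative variance
  (configurable).

**Generalization** is leave-one-out: refit on n−1 subjects, retain by
threshold, project and reconstruct the held-out grid, record the mean
Euclidean distance over corresponding landmarks (point-to-point, the
natural metric under correspondence; a point-to-surface variant would
read lower). The 95% CI of the mean is the normal approximation
mean ± 1.96·sd/√n over subjects — the simplest defensible choice, noted
here because the quantity is reported without a stated CI method in the
literature this mirrors.

## Conventional measurements

Neck length is arc length between markers along the CLL. Angulation uses
least-squares line directions fitted to three low-curvature stretches:
the 15 mm at the proximal end of the available centerline (suprarenal
axis), the central 60% of the neck (neck axis), and the 15 mm at the
distal end (aneurysm axis). Windows immediately adjacent to the markers
were deliberately avoided: that is where the bend transitions
concentrate, and fits across them bias the angle by several degrees.
The operative workstation protocol is not public, so this definition is
a documented stand-in; it recovers generator angles within 2° and is
rigid-motion invariant to 1e-9. Circumferential calcification/thrombus
categories: <25% absent, 25–50% mild (both boundaries inclusive), >50%
moderate.

## Statistics

- **Mann-Whitney U**: midrank ties; exact two-sided p by full
  enumeration over labelings when n1+n2 ≤ 12 (valid under ties, unlike
  the textbook exact tables); otherwise tie-corrected normal
  approximation without continuity correction. All pooled values
  identical → degenerate, p = 1.
- **Fisher exact**: 2×2 standard two-sided hypergeometric; r×2
  (Freeman-Halton) by full enumeration over fixed-margin tables (≤ a few
  thousand at n = 126), Monte-Carlo above an enumeration budget (seeded,
  1e5 draws). Verified against an independent R implementation.
- **Logistic regression**: maximum likelihood, all predictors entered
  simultaneously (no selection). Fitting runs on internally standardized
  predictors (probabilities are invariant; coefficients are reported on
  the original scale). Separation (non-convergence or exploding
  coefficients) triggers an L2-ridge refit with penalty 1e-6·n and a
  flag on the model. Category covariates enter as ordinal 0/1/2 by
  default; dummy coding is available by configuration.
- **ROC**: empirical curve over all thresholds; trapezoid AUC, which
  equals the midrank U/(n1·n2) identity to 1e-10 (asserted in tests);
  sensitivity/specificity at predicted probability ≥ 0.5.
- Reported discrimination metrics are **in-sample (apparent)**, matching
  the design this mirrors; expect optimism, especially for the
  many-predictor combined model at n = 126. No multiple-testing
  correction is applied across modes by default (Holm correction is a
  configuration option).

## Problem sizes used in the test and acceptance runs

The mesh route (surface generation, distal-end detection, plane-mesh
contour extraction) is exercised at full default density (10×360) on
single subjects and on the full 63 + 63 acceptance run. Many-replicate
calibration checks (500-replicate null type-I error, 100-replicate
effect detection) use the generator's closed-form landmark route at
reduced grid density (5×24 and 10×60), chosen so the whole suite runs on
one CPU in a few minutes; the closed-form and mesh routes are asserted
to agree within mesh discretization error, so the reduced runs exercise
the same algebra.

## Known limitations

- Circular cross-sections and a straight neck segment make the synthetic
  shape space low-rank; clinical variance structure (9 modes to 98%) is
  not reproduced, by construction.
- Apparent (in-sample) discrimination metrics; the optional
  cross-validated mode is off by default for fidelity.
- The angulation definition is a stand-in for an unpublished workstation
  protocol.
- Calcification/thrombus are sampled labels with no geometry; their
  regression coding (ordinal) is an assumption.
- The intra/inter-observer variability of marker placement is not
  modeled (markers are exact in the generator).
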