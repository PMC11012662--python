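# Methods

## Coordinate and sign conventions

All geometry is defined in the raster image frame: origin at the
top-left pixel, x increasing rightward, y increasing **downward**, units
raw pixels. Side labels are patient-anatomical; in a back view the
patient's left appears on the image left, so every left landmark must
satisfy `left.x < right.x` (violations are hard validation errors —
they almost always mean swapped sides, which would silently flip the
sign of every parameter).

The tilt sign rule — clockwise positive for a viewer standing behind
the patient — becomes, in this y-down frame, simply
`atan2(y_R − y_L, x_R − x_L) > 0` when the patient's right-side point
is lower in the image. The rule is locked by unit tests on horizontal,
+45° and hand-computed oblique pairs.

No calibration is supported by design: every reported parameter is an
angle or a left/right ratio, so pixel scale cancels. The raw per-side
region areas (px²) remain available for inspection but are not
comparable across photographs.

## Geometric constructions

**Waistline angles.** LWA/RWA are taken as the interior angle at the
minimal-waist point between the rays to the same-side axilla point and
same-side iliac-crest point. This construction uses only the nine
declared landmarks, is scale-free, and yields obtuse values
(~130–165°) in realistic configurations. Published descriptions of
waistline-angle photogrammetry differ in detail and the original
instrument's exact construction is not recoverable; this one is the
package's documented choice, and WAD = LWA − RWA with the sign
retained (a negative WAD means the right flank is straighter).

**Hemitrunk regions.** The C7 plumbline is the vertical through the
tagged C7 point; the C7-foot point sometimes drawn in clinical figures
is treated as a construction, not a tagged landmark. Each hemitrunk is
split cranio-caudally into shoulder (shoulder→axilla level), waist
(axilla→waist) and pelvic (waist→iliac) quadrilaterals bounded
medially by the plumbline. Where left and right landmark heights
differ, each side's polygon corners on the plumbline take the
*same-side* landmark heights. This keeps every region a simple
quadrilateral, is exactly symmetric under mirroring, and makes the
left and right region pair independent of the opposite side's
landmarks. Areas use the shoelace formula (orientation-independent,
absolute value); tests cross-check it against shapely and against a
Monte-Carlo point-in-polygon estimate.

**Area parameters as ratios.** SA/WA/PA/TA are reported as left/right
ratios (TA pools the three regions, so it always lies between the
smallest and largest region ratio — the mediant inequality, asserted
on every profile). Ratios keep the parameters dimensionless and
calibration-free; differences in px² would depend on camera distance.

**Degenerate inputs** — coincident points defining a waistline angle,
or a plumbline falling outside the trunk at any level — raise typed
errors rather than returning NaN, so annotation mistakes surface in
batch runs. A waist point not strictly between its axilla and iliac
levels only warns: the areas remain well defined.

**Invariances** (all property-tested): translation and uniform-scale
invariance of all ten parameters; mirror antisymmetry (reflecting
about the plumbline and swapping side labels negates the signed
angles, swaps LWA↔RWA and inverts each ratio); strict monotonicity of
TA in the plumbline position.

## Reliability model

Each measure's complete subject × rater grid is decomposed by the
two-way crossed ANOVA without replication (subjects random; the
summands are verified to add to the total SS). All four two-way ICC
forms are implemented; the study-runner defaults are:

- **Inter-observer (reproducibility):** average-measures absolute
  agreement, ICC(A,k), on occasion 1. Rationale: the published
  per-measure ICCs of the reference study track 1 − 1/F (the
  average-measures consistency value, an exact identity asserted in
  tests) closely from below, which is the signature of an
  average-measures agreement form.
- **Intra-observer (repeatability):** single-measures consistency,
  ICC(C,1), on each rater's subject × occasion grid (k = 2).

Both are overridable, and every report header records the form used.
Confidence intervals use the exact F-based intervals for consistency
forms and the Satterthwaite construction (with the Spearman–Brown
step-up for the average form) for agreement; values and intervals are
cross-checked in tests against pingouin and an independent elementwise
sums-of-squares oracle (1e-10). A zero MSE (e.g. identical raters) is
reported as an exact ICC of 1 with an infinite F and a degenerate
interval; a tiny floating-point residual SS (below 1e-12 of the total
SS) is snapped to zero so exactly-repeatable grids hit that branch.

**SEM.** SEM = SD·√(1 − ICC). In the descriptives report the SD is the
SD over subjects of the per-photo means across raters at occasion 1,
paired with that measure's inter-observer ICC; this is the pairing
that reproduces the reference study's printed LWA and WAD SEM cells.
(The reference AHA and area SEM cells are not reproducible from any
printed SD/ICC pairing and are not used as checks.)

**Aggregation conventions.** Summary ("Total Mean") rows are
unweighted column-wise means over the ten measures — including the
mean of per-measure minima and maxima for the intra-observer table.
These conventions are validated against the reference study's printed
summary rows; note the source tables print to 2–3 decimals with an
unstated rounding convention, so printed-value checks use one printed
unit as the bound.

**Group comparison** uses the classical pooled-variance two-sided
Student t test at α = 0.05 (no Welch correction, no multiplicity
adjustment — matching standard practice for a 6-vs-6 rater contrast).
Zero pooled variance with equal means returns t = 0, p = 1; with
unequal means it is an error. **Normality screening** is a one-sample
KS test against a normal with the sample mean/SD; because the
parameters are estimated from the same data the p-value is
conservative (Lilliefors caveat), and the flag is advisory only.

## Synthetic cohort

The generator emulates the reference study design: 15 subjects,
12 raters, 2 occasions, on a 1000×1500 px photograph.

- **Template:** fixed anatomical fractions of the image (shoulder span
  0.36 w, axilla span 0.34 w, waist span 0.16 w, iliac span 0.20 w; C7
  above the axilla level on the midline), perfectly symmetric, with
  baseline waistline angles ≈ 152°.
- **Subject effects** (drawn once per subject): independent rigid
  tilts of the shoulder, axilla and waist pairs about their midpoints,
  SD 3° each (so induced SHA/AHA/WHA equal the drawn tilts exactly);
  a C7 horizontal shift, SD 10 px, which moves the plumbline and the
  area ratios; left/right waist-depth perturbations, SD 8 px, which
  vary LWA/RWA. These magnitudes were chosen once to land simulated
  cohorts in the clinically plausible regime (angle SDs of a few
  degrees, area ratios within ±40% of 1, ICCs in the high-reliability
  band the reference study reports).
- **Rater noise:** isotropic Gaussian jitter, SD 2 px by default,
  independently per landmark, rater, occasion and subject — the
  simplest model of mouse-click imprecision, identical for all nine
  landmarks. Optionally a per-rater systematic vertical offset of the
  *right-side* landmarks creates genuine rater main effects (a
  whole-image offset would be invisible, since all parameters are
  translation invariant); this is what separates agreement from
  consistency ICCs in tests.
- **Seeding:** one master seed; each (role, rater, occasion, subject)
  stream is a `SeedSequence(seed, spawn_key=...)` substream, so output
  is byte-reproducible and enlarging the design never perturbs
  existing draws.

For calibration, the first-order angle error from jitter j on a pair
of span s is √2·j/s radians (`expected_angle_error_sd`); with the
default 2 px on the 360 px shoulder span that is ≈0.45°, giving a
population SHA ICC(C,1) of 9/(9+0.2) ≈ 0.98.

**What the simulator does not model:** real photograph acquisition
(pose sway, BMI, clothing occlusion), landmark-specific or correlated
tagging errors, rater learning between rounds, or non-Gaussian
outliers. Passing recovery tests therefore demonstrates that the
geometry and statistics are internally consistent under the stated
noise model — not that real observers behave like the model.

## Problem sizes and numerical choices

Recovery checks use 20 seeded replicates of the full 15 × 12 × 2
design (tolerance ±0.05 on the ICC, ±20% on the SEM — the
single-consistency estimator is mildly biased downward at n = 15,
which the tolerance absorbs); CI coverage uses 500 replicates with an
acceptance band of [0.91, 0.99] around the nominal 0.95; the t-test
type-I rate uses 1000 replicates. All of this runs in a few seconds.
Angles are computed with atan2/acos on clipped cosines; reports round
(ICC 3 decimals, SEM and aggregates 2, angles 2, ratios 3) while the
core never rounds.

## Known limitations

- Only the back view is modelled; lateral and forward-bend metrics,
  and correlations with radiographic or patient-reported outcomes, are
  out of scope.
- The image "quality check" is structural only (completeness, side
  order, vertical ordering, optional minimum resolution): no pixels
  are ever read.
- The waistline-angle construction and the ratio form of the area
  parameters are documented package decisions; other instruments may
  define these differently, so absolute values are comparable only
  within this tool.
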