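# Methods

## Scope and model

`nucleomorph` quantifies nuclear envelope shape defects from single-channel
2D fluorescence images. The underlying model of a "normal" nucleus is a
smooth, convex, roughly elliptical cross-section; dysmorphy manifests as
blebs (convex protrusions) and invaginations (inward folds), both of which
create locally concave boundary arcs. All analysis is therefore built on a
closed sub-pixel boundary per nucleus and three dimensionless descriptors of
its concavity: relative concavity RC, mean negative curvature MNC, and
maximum negative curvature NC_max.

Working in 2D is an assumption, not an approximation that is corrected for:
folds whose geometry only shows in z, chromatin texture, and multi-lobed
(non-star-convex) morphologies are out of scope.

## Segmentation

1. **Detection** — global Otsu threshold on the frame, connected components
   (8-connectivity), hole filling. Objects touching the frame border are
   always excluded (a partial nucleus would bias all three features); a size
   filter (default 200 px² to 25% of the frame) removes debris and
   field-scale artifacts. Otsu is used because it is parameter-free; the
   threshold method is configurable.
2. **Per-object refinement** — the object's bounding box (5 px margin) is
   re-thresholded with Otsu so each nucleus gets its own threshold,
   insulating dim nuclei from bright neighbors and overexposure elsewhere in
   the frame. The traced pixel outline initializes an active contour.
3. **Snake** — classic semi-implicit scheme: with periodic second- and
   fourth-difference matrices D2, D4 and internal matrix
   A = α·D2 − β·D4, the contour iterates
   x ← (I − γA)⁻¹(x + γF(x)), where F is the bicubic-spline gradient of the
   edge energy |∇(G_σ ∗ I)| normalized to [0, 1]. Defaults: elasticity
   α = 0.01, rigidity β = 0.1, step γ = 0.5, 100 iterations, σ = 1 px,
   convergence when the largest point move drops below 10⁻⁴ px. These values
   were chosen so that on rendered test images the contour stays on the edge
   ridge of an ideal circle to well under 0.1 px while still regularizing
   point spacing; an implementation was written in-package after measuring
   that the off-the-shelf active contour available to us settles 0.5–1 px
   away from an analytic ridge even when initialized on it, which alone
   would exceed the area-accuracy target at typical nucleus radii. A
   force-free fallback (`snake.enabled: false`, periodic Gaussian smoothing
   of the traced outline, σ = 2 points) exists for comparisons.
4. **Post-smoothing and resampling** — the refined contour is smoothed with
   a periodic Gaussian (σ = 1 point) to suppress noise-driven zigzags that
   would otherwise self-intersect at high sensor noise, then resampled to
   N = 1000 arc-length-uniform points by cumulative chord length with linear
   interpolation, and oriented counter-clockwise. A contour that still
   self-intersects or falls below the minimum area demotes its object to
   excluded status with a logged diagnostic.

Overlapping nuclei are excluded, not split. The primary mechanism is an
explicit exclusion list (ids per image); an optional automatic rule flags
kept objects with mask solidity < 0.85 *and* at least two strong lobes in
the centroid-to-outline radial profile. The rule is off by default because
exclusion is a judgment call; note that two similar, side-by-side ellipses
never drop below ~0.88 solidity regardless of overlap, so the heuristic is
only expected to catch pairs with distinct geometry (e.g. perpendicular
major axes), which is what the synthetic overlap fixture generates.

Coordinates are x = column, y = row, origin at the top-left pixel center.
Features are computed in pixel units; RC, MNC and NC_max are dimensionless
and the pixel size (default 1/6.22 μm/px) is carried only to report areas
in μm².

## Features

- Enclosed area *a* by the shoelace formula (self-intersecting input is an
  error); hull area *h* from the convex hull of the boundary points;
  RC = (h − a)/h, clamped at 0 against floating-point rounding on convex
  shapes.
- Signed curvature at point *l* from the exact circumcircle of
  (l−w, l, l+w), w = 25 at N = 1000: κ = 2·cross(p₂−p₁, p₃−p₁)/(|e₁||e₂||e₃|),
  which equals ±1/R with the sign of the triple's orientation. Collinear
  triples get κ = 0 and count as non-negative. If N is changed, keeping
  w/N = 0.025 preserves the smoothing scale of the estimator (configurable;
  the window is a resolution/noise trade-off, not a derived quantity).
- MNC = √a · mean |κ| and NC_max = √a · max |κ| over points with κ < 0;
  both are defined as exactly 0 for a boundary with no concave points.
- Eccentricity and orientation come from the central second moments of the
  enclosed region (Green's-theorem closed forms), i.e. the moment-equivalent
  ellipse; eccentricity = √(1 − λ₂/λ₁), orientation in (−π/2, π/2], set to
  0 by convention for a circle (λ₁ = λ₂).

## Classifier

Limits per feature from a labeled training set: **lower** = smallest value
among dysmorphic-labeled nuclei, **upper** = largest among normal-labeled,
**intermediate** = the threshold t minimizing
(#dysmorphic < t) + (#normal > t), searched over midpoints of consecutive
distinct values plus one candidate below the minimum and one above the
maximum, ties resolved toward the smallest t, then clamped into
[lower, upper] (with a logged warning when clamping moves it).

Classification applies four steps strictly in order with strict
inequalities: (1) any feature below its lower limit → normal; (2) any above
its upper limit → dysmorphic; (3) two or more above their intermediate
limits → dysmorphic; (4) otherwise normal. Step 1 deliberately lets a
single small feature veto extreme values of the others — that is the scheme
as specified; `step1_mode: all` is provided as a documented variant. Values
exactly at a limit fall through to later steps, which makes ties
reproducible.

When a feature fully separates the training classes, lower (min dysmorphic)
exceeds upper (max normal). The limits are stored un-swapped in that case:
the step order then resolves the gap (step 1 fires first, so values in the
gap classify as normal), and the intermediate is required to lie between
the two.

Models persist as JSON with a schema version and per-feature limit triples;
loading validates schema, completeness, numeric types, and the limit
invariants.

## Agreement and regression

Cohen's Kappa uses the standard two-rater, two-category formula
κ = (p_o − p_e)/(1 − p_e) with chance agreement from the marginal products;
when both raters are constant and identical, p_e = 1 and κ is returned as
1.0 by convention (logged). Percent agreement is the raw matching fraction.
Both are reported because percent agreement alone flatters raters who
guess.

The age trend of percent-dysmorphic is an ordinary least-squares fit with
t-based confidence and prediction intervals (n − 2 df, 95% default); an
individual's deviation from trend is observed minus predicted percent at
their age, in percentage points. Regressing symptom-onset age on that
deviation reuses the same machinery. Group-level ANOVA/post-hoc testing is
deliberately not re-implemented: the pipeline exports tidy per-sample
tables for standard statistics tooling.

## Synthetic generator

The generator emulates the study conditions end to end: star-shaped nuclei
r(θ) = ellipse radius × (1 + ripple) + Σ Gaussian bumps in polar angle,
with blebs (+) and invaginations (−). Defaults: semi-major 35–55 px
(≈ 11–18 μm at 6.22 px/μm), axis ratio 0.65–0.95, ripple amplitude ≤ 2%,
normal-class bumps below 8% of the local ellipse radius, dysmorphic-class
nuclei carrying at least one bump at 20–45%. A nucleus is labeled
dysmorphic iff some bump reaches 15% of the local ellipse radius — a
quantitative stand-in for by-eye labeling, sized to be an obvious defect at
the default image scale. Rendering fills the analytic polygon at a
foreground level of 10000 on background 500 (16-bit), blurs with a Gaussian
PSF (σ = 1.5 px), then applies Poisson shot noise plus Gaussian read noise
with σ = 2% of the rendered dynamic range (foreground − background);
overexposure is modeled by rendering selected nuclei above the sensor
maximum so they clip to saturation. Everything is driven by
`numpy.random.default_rng(seed)`: identical spec and seed give bit-identical
images.

Boundary sampling inverts arc length on a dense θ grid and re-evaluates the
analytic radial function at the inverted angles, so sampled points lie
exactly on the curve; a circle boundary therefore reproduces κ = 1/r to
floating-point accuracy, and the ≥10⁴-point version of the same boundary
(curvature window scaled to keep w/N fixed) serves as the feature oracle in
tests.

What the generator does *not* emulate: uneven illumination, chromatin
texture inside nuclei, out-of-focus light, stage drift, non-star-shaped
folds, and densely packed fields (one nucleus per frame in the labeled
corpus; overlap fixtures place exactly two). Passing tests on synthetic
corpora therefore demonstrate correctness of the geometry, training and
reporting machinery under controlled imaging physics — not performance on
any particular real specimen.

## Problem sizes and numerical choices

Test corpora use 100–120 rendered nuclei per corpus (256×256 frames, one
nucleus each) and 100–200 analytic nuclei per class for classifier checks;
regression coverage uses 500–1000 simulated replicates at n = 50. Feature
tolerances in the oracle-equivalence tests are 5% relative (10% for NC_max),
with an absolute floor of 10⁻⁹ in the denominator to guard ratios when a
feature is numerically zero (e.g. RC of a convex shape, ~10⁻¹⁵). CSV output
uses a fixed 9-significant-digit float format so repeated runs are
byte-identical.

## Known limitations

- Step 1 of the classifier can override an extreme feature with a single
  small one; this is faithful to the scheme but worth knowing when
  interpreting calls near the lower limits.
- The curvature window (25 points ≈ 2.5% of the perimeter) bounds the
  sharpest resolvable invagination; bites much narrower than the window are
  underestimated in MNC (the mean mixes transition points; NC_max is far
  less affected).
- MNC measured through the imaging pipeline is noise-sensitive: sensor noise
  adds small concave wiggles that inflate it relative to the analytic value,
  which is why classifier limits should be trained on features measured
  through the same pipeline as the nuclei being classified.
- The automatic overlap heuristic cannot detect side-by-side fusions of
  similar ellipses (see above); the exclusion list remains the reliable
  path.
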