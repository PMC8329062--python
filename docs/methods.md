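# Methods

This note documents the models and procedures implemented in `spinemorph`,
the defaults they run with, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The shape model

**Representation.** Each muscle cross-section is a closed, simple,
counterclockwise contour of K = 100 landmarks (configurable), equally spaced
by arc length from a fixed anatomical start point: the boundary point of
maximal medial extent (minimal x in the canonical right-side frame, ties
broken by minimal y).  This arc-length correspondence from a fixed start is
the package's one structural simplification relative to image-space
registration pipelines: it replaces group-wise nonlinear registration with a
point-distribution model, which is adequate for the star-shaped outlines the
generator produces and keeps the whole analysis self-contained.  Coordinates
are physical millimetres; pixels are 0-based, x rightward, y downward, with
pixel centres at (index + 0.5)·spacing — the rasterizer sets a pixel iff its
centre lies inside the polygon (even-odd rule), so rasterization and
boundary extraction are exact inverses up to quantization.

**Boundary extraction and smoothing.** Masks are traced at the 0.5
iso-level.  The pipeline applies a periodic gaussian filter of 1 mm arc
length to the traced boundary before landmark placement
(`extract_contour(..., smooth_mm=1.0)`; the raw trace is available with
`smooth_mm=0`).  This suppresses pixel-staircase quantization noise, which
otherwise adds a broadband noise floor to the shape spectrum: with raw
traces the 90% threshold retains ~15 modes on the default cohort and small
localized effects smear across them; with 1 mm smoothing it retains ~7.
One millimetre equals the default pixel size, attenuates harmonics above
k ≈ 20 on a 20 mm-radius outline, and leaves the injected bulge (harmonics
up to k ≈ 8) nearly intact.

**Canonical side and mirroring.** All left-side shapes are mirrored about
the image vertical midline into the right-side frame; the min-x start rule
is re-applied after mirroring, which keeps landmark 0 at the medially most
extreme point, so correspondence remains anatomically consistent.  Analysis
is performed on one side only; each subject contributes two samples per
muscle per level (affected-side and unaffected-side shape).

**Symmetric template.** The template is the generalized Procrustes mean of
the canonical shapes *and a reflected copy of each*.  Two distinct
reflections exist and the distinction matters:

- `mirror_shape(..., restart=True)` re-applies the start rule — correct for
  mapping a left-side muscle into the canonical frame, but the implied
  landmark relabeling depends on which vertex is most lateral and therefore
  varies from sample to sample;
- `mirror_shape(..., restart=False)` preserves landmark labels (vertex 0
  stays vertex 0, order reversed to restore orientation).  Under this fixed
  involution the template set is exactly reflection-closed, the GPA fixed
  point is reflection-equivariant, and the mean is mirror-symmetric to the
  convergence tolerance (asymmetry measured below 1e-9 in practice, asserted
  below 1e-5).  Template construction uses this form.

Geometrically, the label-preserving reflection mirrors about the axis
through landmark 0 and the centroid; `reflection_alignment()` returns the
rotation relating the reflected template back onto itself, which lets tests
classify every mode of a mirror-closed model as symmetric or antisymmetric.

GPA iterates {similarity-align all shapes to the reference, average
point-wise, re-centre, renormalize centroid size (RMS distance to centroid)
to 1} until the mean moves < 1e-6, erroring after 100 iterations.
Similarity alignment is solved in closed form with complex arithmetic,
which structurally excludes reflections — mirroring is always explicit.
"Linear registration" is thus interpreted as similarity (scale, rotation,
translation); the spec-level alternative (affine) was considered and
rejected because shear/anisotropy would absorb genuine shape signal.

**PCA.** Modes and variances come from the eigendecomposition of the sample
covariance (1/(n−1)) of the stacked 2K-vectors, via the n×n Gram matrix when
2K > n; eigenvalues below 1e-12 of the largest are discarded as numerical
nullspace.  The model retains the smallest M whose cumulative variance
fraction reaches the threshold (default 0.90).  Mode coefficients are
orthogonal projections onto the retained modes; `mode_variant(m, ±3)`
produces the conventional three-standard-deviation visualization shapes.

## Morphometry

CSA is pixel count × spacing² / 100 (cm²).  Fat segmentation is two-class
k-means on within-mask intensities with the higher-mean cluster labelled fat
(T2-weighted convention — fat is bright; inverted-contrast inputs would
silently flip the labels).  The one-dimensional two-class problem is solved
*exactly*: the optimal partition is a threshold on the sorted values, found
by scanning all n−1 splits with prefix sums.  This is deterministic,
globally optimal (the classical interval-clustering property), and
guarantees agreement with an exhaustive minimum-SSW enumeration; iterative
Lloyd refinement from fixed quartile seeds was rejected because it provably
lands in local optima on unstructured inputs.  Dice is 2|A∩B|/(|A|+|B|),
with the both-empty case defined as 1.0 (agreement on nothing is perfect
agreement; logged when it occurs).  Fat% is a proportion internally and
formatted as percent only in reports.  k-means runs per muscle mask (not
per image), since the measure is defined relative to each muscle's CSA.

## Intensity standardization

The two-stage percentile-landmark method: the standard scale is the
per-percentile mean of the per-image foreground percentiles (deciles plus
the 1st and 99th), foreground being the union of the muscle masks; each
image is then mapped by the piecewise-linear transform carrying its own
landmarks onto the standard values, with the terminal segments extended
rather than clipped.  The map is monotone, idempotent on the landmarks, and
exactly cancels per-subject affine contrast jitter.

One deliberate consequence: the *pipeline's* fat segmentation consumes
native intensities, not standardized ones.  Per-mask 1-D k-means is
affine-equivariant, so the per-subject jitter the standardization corrects
is already invisible to it — while the piecewise-linear landmark map can
warp a strongly bimodal within-muscle histogram (landmarks falling in the
sparse fat/lean gap stretch one mode relative to the other) enough to move
the optimal split inside the fat mode for high-fat muscles.  On synthetic
cohorts this raised the worst-case fat-fraction error from ~0.002 to ~0.15.
Rank statistics on fat% are therefore guaranteed invariant to the jitter
itself, but not in general to applying the landmark map before k-means;
the standardized scale remains available (and is written by the pipeline)
for cross-subject intensity comparability and visualization.  Bias-field
correction is deliberately out of scope: inputs are assumed bias-free, as
the generator's are.

## Statistics

Partial Spearman correlation is Pearson correlation of rank residuals: all
columns are rank-transformed (average ranks for ties), the two tested
columns are residualized by least squares on the covariate ranks plus an
intercept, and p comes from t = ρ√((n−2−k)/(1−ρ²)) with n−2−k degrees of
freedom; k = 0 reduces to ordinary Spearman.  The p-value floor is 1e-300;
perfect correlations report that floor.

Per (level, muscle, mode) and per (level, muscle, measure) the three tests
are: side_role (affected = 1) controlling {sex, age}; sex (F = 1)
controlling {age, side_role}; age controlling {sex, side_role}.  Age is
centred (immaterial after ranking, but fixes the sign convention).  The two
sides of one subject enter as independent observations — the analysis
correlates measures against a side indicator rather than using a paired
test; with a genuine within-subject correlation structure this would be
anticonservative, which is a known limitation of the design being emulated.
No multiple-comparison correction is applied (each mode is an uncorrelated
shape variation and each correlation is treated as an independent
exploratory test); reports state this, and a Benjamini–Hochberg column is
available behind `add_bh=True`.  The fat%-vs-modes experiment correlates
fat% with each mode found significant for any factor, controlling
{sex, age, side_role}.

## The synthetic cohort

The generator emulates the cohort structure the analysis assumes, with
every parameter in `CohortConfig`:

- **Covariates**: 24 subjects, exactly 11 female, herniation on the left in
  exactly 15; ages normal (41.5, 7.9²) truncated at 18.
- **Outlines**: star-shaped Fourier radius functions of order 4,
  r(θ) = r₀(1 + Σ aₖcos kθ + bₖsin kθ).  Base radii (20.3, 20.3, 17.8,
  14.2 mm for MF-L5S1/MF-S1/ES-L5S1/ES-S1) put the mean CSAs at the
  magnitudes a lumbar cohort shows (MF ≈ 13 cm², ES ≈ 10 and 6.5 cm²).
  Coefficient noise has sd 0.02/k^1.5 — the 1/k decay encodes a
  smooth-contour prior and is what allows a narrow localized bump to occupy
  its own PCA direction instead of mixing into low-order noise.
- **Effects**: females' a₂ (mediolateral elongation) +0.03; elongation
  +0.0012/year; radius −0.4%/year.  The pathology effect is a gaussian
  radial bulge (amplitude 0.8 mm, angular width 0.12 rad) at the medial
  angle (π in the right-side frame, mirrored for left), applied only to the
  affected-side multifidus at S1.  At these settings the injected
  between-group bulge variance is ≈5% of total shape variance (measured
  against matched null cohorts, which is exact because the bulge consumes
  no random draws), the side test detects it in ≈100% of cohorts, and the
  implicated mode's ±3 SD variant peaks medially in >90%.
- **Intensities**: equal-variance two-gaussian mixture (lean 60, fat 140,
  σ 10 — the minimal model under which 2-means is a consistent separator),
  background at half the lean mean; within each mask a smoothed noise field
  is thresholded at the exact quantile so the realized fat-pixel count is
  round(f·|mask|); fat fractions are logistic in sex and centred age with a
  per-muscle offset (MF ≈ 26%, ES ≈ 42% on average).  Per-subject affine
  jitter (scale 0.8–1.2, shift ±10) gives the standardization stage real
  work.
- **Determinism**: one root seed; covariates, shapes, and intensities draw
  from separate `SeedSequence` substreams, so disabling image synthesis
  never perturbs the shapes.

What the generator does **not** emulate: 3-D anatomy, vertebral bone or the
ilium's constraint on muscle geometry, non-star-convex outlines, MRI bias
fields, Rician noise, or continuous (non-bimodal) fat distributions.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under these idealized conditions, not clinical validity on real
scans.  The synthetic mode spectrum is also simpler than a real cohort's —
one dominant elongation mode plus a localized pathology mode — so retained
mode counts (~7 at 90%) should not be read as an anatomical finding.

## Numerical choices and degenerate inputs

- Contour validity: simplicity via polygon validity checks; counterclockwise
  enforced; consecutive duplicate vertices rejected.  Non-positive Fourier
  radii are rejected naming the offending angle.
- Start-point tie-break (min x, then min y) makes correspondences
  reproducible across platforms.
- GPA convergence 1e-6 (mean-shape RMS change), max 100 iterations;
  alignment of a zero-size contour errors.
- Rank ties use average ranks everywhere; zero-variance rank residuals are
  a degenerate-input error rather than a silent NaN.
- Pipeline CSVs are written with a fixed float format, making reruns with
  the same config and seed byte-identical.
- Study sizes in the simulation harnesses (50 cohorts for effect recovery,
  200 for null calibration, 24 subjects each) were chosen to keep the whole
  suite under a minute while leaving the binomial acceptance bands
  meaningful.

## Known limitations

- Arc-length correspondence from a single anatomical anchor is cruder than
  registration-derived correspondence; it can slide landmarks tangentially
  where local geometry changes (visible as small tangential components in
  mode fields).
- Treating the two sides of a subject as independent ignores within-subject
  correlation (discussed above).
- The radius-function family cannot represent non-star-convex muscle
  sections; real MF/ES outlines at some levels are not star-convex.
- The t-approximation for partial Spearman p-values is asymptotic; at
  n = 48 the realized type-I rate sits near, but not exactly at, the
  nominal 5% (the calibration test brackets it with an exact binomial
  band).
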