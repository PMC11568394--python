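# Methods

This note documents the models, numerical choices and limitations behind
`cobbkit`: the automatic Cobb-angle pipeline, the synthetic spine generator
used to validate it, and the agreement statistics.

## Coordinate and data conventions

All geometry lives in image pixel coordinates with the origin at the top
left and y increasing caudally, the raster convention of a standing
full-length radiograph.  A vertebra is four corner keypoints in the fixed
order UL, UR, LR, LL; the order is validated (upper corners must be cranial
to lower corners, the quadrilateral must be simple) and never inferred,
because a silently re-ordered corner would corrupt the endplate lines that
every angle is built from.  Angles are dimensionless (degrees), so pixel
spacing is carried as metadata only.

## Centerline: moving least squares

The centerline is parametrized as lateral displacement x as a function of
y — appropriate for roughly vertical spines and documented to degrade for
more than ~45° of axial tilt, where x(y) stops being single-valued.  At each
of `grid_size` (default 200) query points spanning the centroid range, a
local quadratic is fitted to the vertebral centroids by weighted least
squares with a Gaussian kernel w(Δy) = exp(−Δy²/2h²) and evaluated at the
query point.  The quadratic basis reproduces any polynomial of degree ≤ 2
exactly, for any bandwidth — the property the unit tests pin down to 1e-9 px.

The bandwidth h defaults to **2× the median inter-centroid spacing**
(≈ 94 px for the default 17-vertebra / 800-px synthetic spine).  Smaller
bandwidths track sharper curves but amplify keypoint noise; 2× spacing keeps
the worst-case deviation from a noiseless sinusoidal centerline below 2% of
its amplitude over the interior of the spine while averaging roughly four
vertebrae of noise at each query point.  A numerically singular local system
(possible only for degenerate centroid configurations) falls back to a local
linear fit and records a warning.

## Inflection points and segmentation

A single global polynomial (default degree 6, fitted on the centered/scaled
ordinate for conditioning, coefficients reported in original coordinates) is
fitted to the sampled centerline, and its analytic second derivative is
evaluated on the grid.  Degree 6 resolves up to three interior inflections —
a double-curve scoliosis plus compensatory bends — without the oscillation a
much higher degree would add; it is configurable.  The fit is global rather
than piecewise: the curve being differentiated is already smooth, and a
global polynomial gives a single analytic x″ with no knot artifacts.

Segment boundaries sit at sign changes of x″, linearly interpolated between
grid points.  Two guards handle degeneracy: values of |x″| below a dead band
of 1e-12 · ptp(x)/span² (machine-noise scale for a straight spine) are
treated as zero so an arrow-straight spine yields exactly one segment, and
segments holding fewer than two vertebrae are merged into the neighbouring
segment with the larger mean |x″| (two vertebrae being the minimum that can
define a Cobb angle).  After merging, any same-direction adjacency is
collapsed, so the output always alternates bending direction and partitions
the vertebra list.  Segmentation operates on the fitted centerline, not the
raw centroids, so one noisy centroid cannot create a spurious segment.

## Cobb angle per segment

The superior endplate line of vertebra i and the inferior endplate line of
vertebra j are the lines through the corresponding corner pairs (exact
interpolation — two points determine the line).  The search enumerates all
pairs with i ≤ j inside the segment: the anatomical Cobb convention (upper
endplate of the cranial end vertebra against lower endplate of the caudal
one), with i = j permitted, which measures single-vertebra wedging.  The
intersection angle is computed as arccos |d₁·d₂| on unit direction vectors,
which equals arctan |(m₁−m₂)/(1+m₁m₂)| wherever both slopes exist and is
robust for vertical endplates; the equivalence is enforced by test to 1e-9°
over 10⁵ random slope pairs.

Angles below the 5° floor are discarded *per pair, before maximization*; a
segment where every pair falls below the floor yields no measurement rather
than 0°, because an unmeasurable curve is not a measured small curve.  Ties
at the maximal angle are broken toward the longest vertebral span (j−i),
then the most cranial i — a deterministic convention, relevant mainly to
noiseless synthetic data where exact ties occur.  Across segments, the
largest angle is the major curve and the second largest the minor; severity
(mild <25°, 25°≤moderate≤45°, severe >45°, boundaries inclusive to moderate)
is classified from the major angle.

## Synthetic spines and ground truth

The generator emulates the detector's output contract — four corners per
vertebra, cranial→caudal — on spines whose centerline is a sum of sinusoids
x(y) = Σ Aᵢ sin(kᵢy + φᵢ) over y ∈ [0, L].  Vertebrae are rigid rectangles
centred on the centerline at equal y spacing, rotated so their endplates are
exactly perpendicular to the local tangent.  That choice makes the true
orientation of each vertebra arctan(dx/dy) at its centroid, and the true
Cobb angle of a segment exactly the max−min orientation over its member
vertebrae — ground truth is defined discretely, on the vertebrae the
algorithm can actually see, which removes discretization bias from recovery
tests.  Defaults (17 vertebrae, 800-px span, 60×40-px bodies) emulate a
full-length standing film at typical detector resolution; corner noise is
i.i.d. isotropic Gaussian, the simplest detector-error model, at 1 px for
the noisy-recovery studies.

What the generator does **not** model: vertebral rotation, wedging,
endplate curvature, 3D-to-2D projection, sagittal curves, and non-Gaussian
or spatially correlated detector failures.  Passing recovery tests therefore
show the geometry engine is correct, not that any upstream keypoint detector
is accurate on real radiographs.

`analytic_cobb` doubles as an independent oracle: it partitions the dense
analytic x″ by sign (bisection-refined zeros) and takes max−min orientations
per interval, with no shared code with the measurement path.

For the agreement statistics, `simulate_paired_measurements` draws
measurement = truth + method bias + N(0, sd²) per replicate (negative draws
clamped at zero and counted), and `simulate_crossed_design` draws fully
crossed subject × rater tables with N(mean, between_sd²) subjects — giving
a population ICC of between_sd²/(between_sd² + error_sd²) to recover.
The default simulated error of 1.75° per method reproduces the ±≈4.9°
limits-of-agreement regime typical of automatic-vs-manual comparisons.

## Agreement statistics

The ICC form is **ICC(2,1)** — two-way random effects, absolute agreement,
single measures — used for both inter-observer and intra-observer (per-rater,
columns = replicates) analyses; it is the standard choice for method
comparison, where systematic offsets between raters should count against
agreement.  The estimate comes from the classical mean-squares
decomposition, the 95% CI from the standard F-based interval, and the
p-value from F = MS_R/MS_E on (n−1, (n−1)(k−1)) degrees of freedom; the
implementation is verified against an independent ANOVA oracle to 1e-10 on
small integer tables.  Bands: <0.25 below-poor, 0.25–0.499 poor, 0.5–0.699
moderate, 0.7–0.899 good, ≥0.9 excellent.

Bland-Altman limits of agreement use exactly mean ± 1.96·SD with the sample
SD (n−1 denominator) — the z-multiplier, not a t-quantile, and no CI on the
limits themselves.  The accuracy rate counts |difference| **strictly** below
the 5° clinical allowance.  Stratified reports assign severity from the
*reference* method's angle (grouping by the manual measurement, not the
method under test); strata with fewer than three pairs report MAE/accuracy
but no Bland-Altman statistics, and empty strata report n = 0 with nulls.

End-vertebra offset tables compare the major curve's upper and lower end
vertebrae between two paired report lists, in vertebral levels (positive =
method A more caudal), binned at −2…+2 plus "other".

## Problem sizes

The validation studies run at sizes chosen to make Monte-Carlo error small
relative to the effects tested: 10⁵ slope pairs for the angle-formula
equivalence, 500 random segments for the search oracle, 200 noisy spines for
the MAE regime, 100 straight spines for the floor behaviour, 5000×2 designs
for ICC recovery, 50×802 pairs for the limits of agreement, and 670 paired
reports for the offset multinomial.  All are seeded and complete in seconds.

## Known limitations

- x-as-function-of-y parametrization fails for extremely tilted or
  horizontal spines (>~45° local tilt).
- The 5° floor means genuinely small curves are reported as "no measurable
  curve"; this is by design but makes the tool unsuitable for quantifying
  sub-5° asymmetry.
- Segments are independent: the search never pairs endplates across an
  inflection, so a curve whose clinical end vertebra lies just beyond the
  detected inflection is attributed to the neighbouring segment.
- ICC confidence intervals assume the balanced, complete two-way normal
  model; unbalanced designs are rejected rather than approximated.
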