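# cobbkit

Automatic Cobb-angle measurement for scoliosis from per-vertebra corner
keypoints, together with the reliability statistics used in method-comparison
studies and a synthetic spine generator with analytic ground truth.

## Who this is for

The Cobb angle — the angle between the superior endplate of the most tilted
cranial vertebra and the inferior endplate of the most tilted caudal vertebra
of a curve — is the standard quantitative index of scoliosis severity.
Keypoint detectors can now place the four corners of every vertebral body on
a full-length spine radiograph; `cobbkit` turns that detector output into
Cobb angles, fully automatically, and provides the statistical machinery to
validate such a pipeline against a manual reference method.  It is a library
first (with a thin `cobbkit` CLI), aimed at researchers building or
evaluating automatic scoliosis measurement systems.

## The algorithm

Given an ordered cranial→caudal list of vertebrae, each with corner
keypoints (UL, UR, LR, LL) in image coordinates:

1. **Centerline.** The lateral displacement *x(y)* of the spine is fitted to
   the vertebral centroids by **moving least squares**: at each point of a
   dense grid, a local quadratic is fitted with a Gaussian kernel
   (bandwidth 2× the median inter-centroid spacing by default) and evaluated
   at that point.
2. **Inflections.** A global polynomial (degree 6 by default) is fitted to
   the sampled centerline; its analytic second derivative *x″(y)* locates the
   inflection points.  Sign changes of *x″* split the spine into oppositely
   bending **segments**.
3. **Angle search.** Per segment, a line is fitted through each vertebra's
   superior and inferior endplate corners, and a loop iterates over all pairs
   (superior endplate of vertebra *i*, inferior endplate of vertebra *j*,
   *i* ≤ *j*).  The intersection angle is

   θ = arctan |(m₁ − m₂) / (1 + m₁m₂)|,

   evaluated in the equivalent direction-vector form θ = arccos |d₁·d₂| so
   vertical endplates need no special case.  Angles below **5°** are ignored;
   the largest surviving angle is the segment's Cobb angle and its two
   vertebrae are the curve's end vertebrae.
4. **Report.** The two largest segment angles become the **major** and
   **minor** curves; severity is mild (<25°), moderate (25–45°) or severe
   (>45°).

The agreement module provides ICC(2,1) (two-way random effects, absolute
agreement, single measures, with F-based 95% CI and the
poor/moderate/good/excellent bands), Bland-Altman 95% limits of agreement
(mean difference ± 1.96 SD), mean absolute error, the strict <5° accuracy
rate, severity-stratified versions of all of these, and end-vertebra level
offset tables between two methods.

## Worked example

```sh
python examples/01_measure_synthetic_spine.py
```

```
true segment angles : ['44.09', '39.93'] deg
measured major      : 42.26 deg (vertebrae 0-8)
measured minor      : 38.41 deg
severity            : moderate
```

An S-shaped synthetic spine with 1-px keypoint noise: the pipeline finds both
bending segments and recovers each true angle to within about 2°, the error
regime expected from pixel-level corner noise on 60-px-wide vertebrae.
With the noise set to zero the recovery is exact to machine precision.

```sh
python examples/02_agreement_statistics.py
```

```
ICC(2,1)      : 0.990 (excellent), 95% CI [0.988, 0.991]
Bland-Altman  : mean diff +0.10 deg, LoA (-4.92, 5.12) deg
MAE           : 2.03 deg
accuracy <5°  : 94.5% (756/800)
```

Two simulated methods with 1.75° measurement error each: the limits of
agreement land at ±1.96·√2·1.75 ≈ ±4.85° around the injected 0.1° bias, and
the ICC reflects the large between-subject spread relative to that error.

The same operations are available from the shell:

```sh
cobbkit simulate --curve-angle 35 --seed 7 --out spine.json
cobbkit measure spine.json --out report.json --csv-out report.csv
cobbkit agree measurements.csv --reference PACS --out agreement.json
```

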