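# Methods

This note records the models, conventions and numerical choices behind each
quantification stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Asymmetric index

The ASI treats the equatorial cortex as a closed 1-D profile of *n* equally
spaced intensity samples (*n* even, ≥ 8; default arc spacing 0.108 µm, the
confocal pixel).  For every cyclic window of *n*/2 samples the summed
intensity is compared with the complement and the maximum normalised
difference is reported.  The O(n) implementation doubles the array, takes
prefix sums, and slides the half-window over all *n* starts; ties break to
the smallest start index.  Properties that follow from the definition and
are enforced by tests: invariance under rotation, orientation reversal and
positive intensity scaling; 0 ≤ ASI ≤ 1; adding a constant baseline strictly
decreases a non-zero ASI (the numerator is unchanged, the denominator
grows).

Profile extraction from an image resamples the traced contour to uniform arc
spacing with an even count (linear interpolation along arc length — the
pixel-wise definition presumes a divisible perimeter) and averages bilinear
samples across a 0.5 µm band perpendicular to the contour.  Averaging rather
than summing across the band makes profile values independent of band
discretisation; the ASI is invariant to that choice anyway.

Polarity classification uses a strict cutoff ASI > 0.35, the upper end of
the fluctuation range of membrane-bound GFP, which has no capacity to
polarize.  Cohort summaries report the sample mean, s.d. (n−1), polarized
fraction, and a histogram with 0.05-wide bins on [0, 1].

## Membrane curvature

Curvature is the radius of the circle through three points of a membrane
region — both endpoints and the point at half the region's arc length
(arc-length midpoint, not coordinate average).  R = abc/4A; triangles with
area below 1e-9 µm² are treated as straight (beyond measurement precision)
and the region is excluded with an explanatory note rather than poisoning
group statistics.  Radii are not capped.

Region classification on the closed contour: island spans longer than 1 µm
are islands; membrane within 5 µm geodesic arc distance of an island edge is
"neighboring" (classified so the partition covers the contour, but not
measured — its curvature is confounded by the adjacent island); the
remaining stretch of each inter-island gap is cut into consecutive
compartments of at most 5 µm starting at the exclusion boundary, the last
compartment keeping the remainder.  Cells without islands are cut into ≤ 5 µm
compartments over the whole contour (5–6 per cell at typical S2 perimeters).
The splitting rule is a declared convention: only the 5 µm compartment
length and the 5 µm exclusion distance are constrained by the measurement
design.

## Meshwork periodicity

The contour-length density is a Gaussian KDE evaluated explicitly on a
512-point uniform grid spanning [0, max + 3h]; the default bandwidth h is
Silverman's rule of thumb, 0.9·min(sd, IQR/1.34)·n^(−1/5), and the curve is
renormalised to unit trapezoidal integral.  The bandwidth is exposed
everywhere because peak resolvability depends on it: for a comb of spacing
~0.38 µm with component sd ~0.023 µm, the rule of thumb (driven by the
overall spread, h ≈ 0.18 µm) merges neighbouring teeth, while h ≈ 0.03 µm
preserves them.

The 7-Gaussian comb fit minimises squared residuals of
y(x) = Σ A_j exp(−(x−μ_j)²/2σ_j²) with bounds A_j ≥ 0, σ_j > 0, μ_j inside
the grid.  Initialisation: means evenly spaced across the grid, σ_j = KDE
bandwidth, A_j = density at μ_j; on optimizer failure up to 10 seeded random
restarts, keeping the best residual.  Components are reported sorted by
mean; the peak interval is the mean (± s.d.) of the k−1 consecutive mean
differences.  The fit is robust to the oversmoothed rule-of-thumb density —
the component means still spread over the comb's support — which is why the
recovery study (spacing within 10% of truth for Δ ∈ [0.3, 0.5] µm in ≥ 90%
of 754-length samples) passes with default settings.

The spectral route takes the second derivative of the density by central
differences (suppressing the smooth envelope, which would otherwise dominate
the spectrum), zero-pads to the next power of two, and reports the squared
magnitude of the FFT.  The major frequency is the argmax over positive
frequencies, zero bin excluded, ties to the lowest frequency.  Two numerical
effects matter:

* **Harmonics.** The second derivative multiplies spectral amplitude by
  (2πf)², so for very narrow comb teeth the second harmonic of the comb
  frequency can out-power the fundamental.  An analysis bandwidth of
  ~0.06 µm damps the harmonic (Gaussian smoothing decays as
  exp(−(2πfσ)²/2)) while keeping the fundamental; this is the default for
  the pipeline's spectral stage.
* **Periodicity flag.** A spectrum is flagged periodic only if the dominant
  peak reaches twice the median positive-frequency power *and* its quality
  factor (peak frequency / half-power width) reaches 2.  An aperiodic
  unimodal density produces a broad bump with Q ≈ 1 at a frequency set by
  its own width; a density with several comb periods produces a sharp line
  with Q ≳ 7.

The comb fit and the spectrum are kept as genuinely independent routes; on
simulated 754-contour samples at Δ = 0.38 µm they return ~0.38 µm and
~0.36 µm respectively, the same ~10% level of agreement seen between the
two published estimates of the unit length (0.38 vs 0.42 µm).

Segment statistics: lengths are straight endpoint distances (corners are
encoded by the tracer as segment endpoints); widths are FWHM =
2√(2 ln 2)·σ of a Gaussian-plus-constant-baseline least-squares fit to the
cross-section, requiring ≥ 7 samples and an interior peak.  Where the
literature is ambiguous between "half width" meaning FWHM or FWHM/2, the
explicit FWHM definition is used.

## Geometry and statistics

ROI areas use the shoelace formula with absolute value (orientation-free)
after verifying the polygon is simple; aggregates touching the
optical-section limit are excluded upstream via an input flag.  The fan
test uses image coordinates (y down) with clockwise-positive angles:
θ1 is the clockwise angle from the crescent edge *a* direction to edge *b*,
θ2 from edge *a* to the centrosome; the centrosome is inside the fan iff
0 ≤ θ2 ≤ θ1, boundaries inclusive, so measurement noise cannot exclude a
centrosome sitting exactly on an edge.  Which edge anchors θ2 is encoded by
the input ordering.  Expression ratios divide each blot intensity by its
transfection efficiency before taking the ratio.  Fisher's exact test
(two-sided, scipy) is Bonferroni-adjusted by the number of comparisons,
capped at 1; the test suite checks it against a direct hypergeometric
enumeration.

## Synthetic data

Generators draw all randomness from `numpy.random.default_rng(seed)`, so a
fixed seed is reproducible across platforms; every generator emits a
ground-truth record, and each noiseless output round-trips exactly through
its analysis (ASI, radius, spacing, FWHM, fan flags).  Conditions default to
the observed scales: 0.108 µm confocal and 0.053 µm super-resolution pixels,
cell radii 3.5–5 µm, island radii 1–2.5 µm, 754 contour lengths from a
7-component comb at Δ = 0.38 µm with component sd 0.06·Δ, 194 segments at
0.39 ± 0.09 µm, 0.23 µm FWHM cross-sections, 40-cell fan cohorts at 80%
inside.  Noise models: additive Gaussian clipped at zero for intensity
profiles and images (fluorescence is non-negative); comb lengths falling at
or below zero are re-drawn, not clipped, keeping components Gaussian;
coordinate jitter is isotropic Gaussian.  Crescent placement is uniform —
the ASI is rotation invariant, so placement is immaterial.

What the generators do **not** emulate: point-spread-function blur beyond a
finite line width, shot-noise statistics, autofluorescence background
structure, tracing error of a human annotator, cell-to-cell correlation, or
temporal dynamics.  Passing tests therefore demonstrate the correctness of
the statistics on data with the stated structure, not robustness to every
artefact of real microscopy; analyses of real data should treat tracing
quality and background subtraction as separate concerns upstream of this
package.

## Problem sizes and determinism

Default problem sizes (400-sample profiles, 754 contour lengths, 50-seed
recovery studies, 100-seed noise studies, 1000 random circles) mirror the
study's sample sizes while keeping a full test run under a minute of compute
per module.  Pipeline runs write a JSON report with the resolved
configuration, seeds and per-stage input checksums; two runs with the same
configuration are bit-identical.

## Known limitations

* Island spans and contour traces are inputs (the original measurements were
  manual); no detection of islands from raw fluorescence is attempted.
* The comb fit fixes k = 7 by default; k well above the number of resolvable
  modes leads the optimizer to place duplicate components, surfacing as a
  large peak-interval s.d. rather than an error.
* The KS test is used as published for group comparisons; it is sensitive to
  any distributional difference, not specifically to location shifts.
* The spectral interval is quantised to the FFT grid (one bin ≈ 0.33 µm⁻¹ at
  512 grid points over ~3 µm), so sub-bin agreement with the comb fit is not
  expected.
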