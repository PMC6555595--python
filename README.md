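# parcortex

Quantification of reconstructed Par-complex cortical polarity in *Drosophila*
S2 cells.

When Par3 is overexpressed in normally apolar S2 cells, the Par complex
(Par3 / Par6 / aPKC) assembles on the cell cortex into dots, then
micron-scale "islands" with an internal meshwork of ~0.4 µm unit segments,
and finally a polarized crescent.  This package implements the measurement
statistics used to characterise that process from traced microscopy data —
and a seeded synthetic-data generator so every stage can be verified against
known ground truth without the original images.

## What it computes

**Asymmetric index (ASI).**  For a closed equatorial intensity profile
sampled at *n* equally spaced arc positions (*n* even), with window sums
*S<sub>w</sub>* over all cyclic half-perimeter windows and total *T*:

    ASI = max_w |S_w − (T − S_w)| / T

0 for a uniform cortex, 1 for fully one-sided signal.  Cells with
ASI > 0.35 (strict) are classified as polarized; the cutoff is the upper
bound of the ASI fluctuation range of membrane-bound GFP, which cannot
polarize.  Computed in O(n) by prefix sums; tested against the exhaustive
O(n²) window oracle to 1e-12.

**Membrane curvature.**  Each membrane region contributes the circumradius
of the circle through its two endpoints and arc-length midpoint,
R = abc / 4A.  Regions are classified relative to Par-islands: island spans
(> 1 µm along the contour), neighboring membrane (within 5 µm geodesic arc
distance of an island edge; classified but not measured), and non-neighboring
compartments (≤ 5 µm, beyond the exclusion zone).  Groups are compared by
two-sample Kolmogorov–Smirnov tests.

**Meshwork periodicity.**  Contour lengths of the island meshwork are
comb-distributed at integer multiples of the unit-segment length Δ.  Two
independent routes estimate Δ: (1) a Gaussian KDE of the lengths fitted with
a sum of 7 Gaussians by non-linear least squares — the mean consecutive
difference of the sorted component means is the peak interval; (2) the FFT
power spectral density of the second derivative of the density curve — the
major frequency *f* gives an implied interval 1/*f*.  Segment-level
statistics (straight lengths; FWHM = 2√(2 ln 2)·σ of Gaussian-fitted
orthogonal cross-sections) complement the contour analysis.

**Geometry and cohort statistics.**  Shoelace areas of Par-aggregate ROI
polygons; the fan test (is the centrosome direction from the cell center
inside the angular sector θ1 spanned by the crescent, measured clockwise in
image coordinates?); per-cell expression ratios from western-blot
intensities normalised by transfection efficiency; Fisher's exact test with
Bonferroni correction for polarized-cell fractions.

## Worked example

```sh
python analysis/01_simulate_inputs.py     # seeded synthetic bundle
python analysis/02_asi_polarity.py
python analysis/04_meshwork_periodicity.py
```

prints (seed 0):

```
ASI over 50 cells: mean 0.526 ± 0.123 (s.d.), 90% polarized (ASI > 0.35)
max |ASI - truth| = 0.0114 (noise-limited; the statistic itself is exact)
7-Gaussian comb fit over 754 contours: peak interval 0.387 ± 0.024 um
spectral route: major frequency 2.75 um^-1 -> interval 0.364 um (periodic: True)
```

The simulated cohort has crescents covering 15–60% of the perimeter at 2–8×
contrast, so most cells exceed the 0.35 polarity cutoff; each measured ASI
agrees with the generator's ground truth to ~0.01 (the residual is photon
noise, not the statistic).  The 754 contour lengths were drawn from a
7-component comb with Δ = 0.38 µm: the comb fit recovers 0.387 µm and the
spectral route 0.364 µm — two independent estimates agreeing within ~10%,
the signature of a real unit segment.

The same stages are available as a CLI
(`parcortex simulate|asi|curvature|meshwork|geometry|run`), e.g.

```sh
parcortex run --seed 1 --out runs/demo   # full pipeline, JSON report
```

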