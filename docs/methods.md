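# Methods

This document records the models, parameter conventions, and numerical
choices behind the `ibrp` package, and the limits of the synthetic data
it validates against.

## Assay model

A bead field is modeled as

```
pixel = background + illumination(x, y) + bead_signal(x, y) + noise
```

where `bead_signal` is nonzero only inside bead disks. For one bead,
the retained prey fluorescence is assumed linear in three inputs:

```
E[intensity_per_ms] = affinity × bait_input × prey_input_per_ms
```

- `intensity_per_ms`: background-corrected mean bead fluorescence,
  minus blank-bead autofluorescence, divided by the exposure time in
  milliseconds. Exposure normalization makes measurements from
  different exposures commensurable; dividing counts by milliseconds is
  exact for an ideal linear camera.
- `prey_input_per_ms`: mean fluorescence of a lysate image minus that
  of a mock (prey-free) lysate image, each exposure-normalized. The
  mock subtraction removes lysate autofluorescence.
- `bait_input`: the loaded bait amount (e.g. µg/µl), taken as metadata.

The *IBRP affinity* of a condition is the per-bead
`intensity_per_ms / (bait_input × prey_input_per_ms)`; its mean and
SD (n−1 denominator) summarize the condition. Within a comparison
set, relative affinities rescale every mean by the largest one, so the
maximum is exactly 100 (implemented as `x / max × 100`, which yields
exactly 100.0 in floating point for the maximum itself). Any constant
factor in the affinity definition cancels under this rescaling.

Corrections are floored at zero: a bead dimmer than the blank, or a
lysate dimmer than the mock, yields 0 with a `floored` flag rather
than a negative value. Beads containing saturated pixels (at the bit
depth's maximum in the raw image) are excluded by default
(`saturation_policy`: `exclude` | `flag` | `ignore`).

## Pipeline parameters (default profile)

| Stage | Parameter | Value |
|---|---|---|
| Denoise | Gaussian radius | 1 px (σ = 1, truncated at 4σ) |
| Background | rolling-ball radius | 400 px |
| Threshold | method | Otsu (foreground strictly above the cut) |
| Split | watershed | on distance transform, h-maxima seeds (h = 1) |
| Filter | area | 200 px² – ∞ |
| Filter | circularity | 0.60 – 1.00 |
| Filter | edges | particles touching the border excluded |

These defaults live in `PipelineConfig()`; every run log records a
SHA-256 digest of the active configuration.

## Numerical choices

**Rolling-ball background.** The background is the grayscale opening
of the image with a spherical-cap structuring function
`b(x, y) = sqrt(r² − x² − y²)`, computed with
`scipy.ndimage.grey_erosion/grey_dilation` (border mode `reflect`).
This is exact (it matches a brute-force per-pixel window scan to
machine precision) for radii ≤ 64. For larger radii — including the
default 400 — the image is downscaled by `ceil(r/32)` (bilinear),
opened at the reduced radius, upscaled (cubic), and clipped from above
by the original image so the lower-envelope contract
`background ≤ image` survives interpolation. Library rolling-ball
implementations were measured to deviate from the exact opening by
several counts on noisy images, so the opening is computed directly.
The corrected image is `max(image − background, 0)`.

A caveat measured during development: when the ball footprint
(2r + 1 px) exceeds the image extent, border reflection dominates the
opening and background gradients are followed poorly. With the default
radius 400 this matters only for images much smaller than the intended
~1000×1400 px fields.

**Perimeter and circularity.** Circularity is `min(1, 4πA/P²)` with
the area in pixels and the perimeter measured as the length of the
sub-pixel 0.5-level iso-contour of the binary mask (marching squares on
a zero-padded mask). Integer chain-code and weighted boundary-step
perimeter estimators were evaluated and rejected: they overestimate the
circularity of elongated shapes enough that a 3:1 ellipse of area
2000 px² scores above 0.6 and would evade the roundness filter. With
the iso-contour convention a rasterized disk of radius 30 px scores
0.906 and the 3:1 ellipse 0.599.

**Watershed.** Foreground masks are split on the negated Euclidean
distance transform. Seeds are h-maxima (h = 1 px) of the distance map,
labeled with 8-connectivity; the flood uses the scikit-image watershed
with 1 px separating lines. The flood itself uses 4-connectivity: the
installed scikit-image's watershed exhausts memory when watershed lines
are combined with 8-connectivity on megapixel masks (an upstream
defect); with 4-connectivity the two-disk fixture still splits into
two labels whose areas are within 6% of a single disk.

**Otsu threshold.** `skimage.filters.threshold_otsu`, verified in the
tests against an exhaustive search over all observed gray levels
maximizing between-class variance. A uniform image has no valid
threshold and is reported as an error ("no particles retained" at the
CLI level).

**Welch's t-test.** Implemented from the defining formulas
(Welch–Satterthwaite degrees of freedom, two-tailed p from the
Student-t survival function) and verified against
`scipy.stats.ttest_ind(equal_var=False)` to 1e-10. Two identical
samples return t = 0, p = 1; two zero-variance samples with different
means are reported as degenerate rather than t = ∞.

**OLS.** Closed-form normal equations with `R² = 1 − SS_res/SS_tot`;
constant *x* is an error (slope unidentifiable), constant *y* returns
slope 0 and, by convention, R² = 0.

**SNR.** Mean intensity over all bead pixels divided by the standard
deviation (n−1) of background pixels, where the background excludes
every particle mask dilated by 3 px (keeping bead rims out of the
noise estimate). Requires ≥ 100 background pixels and nonzero
background variance.

**Determinism.** Every stochastic path flows from an explicit integer
seed; derived seeds are drawn below 2³¹. CSV writers sort rows with a
stable key and format floats with `%.9g`, so identical inputs produce
byte-identical files.

## Synthetic scene generator

Beads are disks with diameters drawn from a normal distribution (10%
CV, truncated at ±3 SD) around the nominal 30 µm (or 90 µm) at
0.5 µm/px; the default canvas is 1040×1392 px. Two radial intensity
profiles are supported: uniform, and "halo"
(`I(r) = I_c + (I_rim − I_c)·(r/R)`, default rim/center ratio 3),
modeling large beads that prey penetrates incompletely, so their rims
outshine their centers. Placement is rejection sampling with a 4 px
clearance; a configurable fraction of beads is placed as touching
pairs at 0.83× the sum of radii (overlapping pixels belong to the
nearer center). Illumination can be flat, a planar tilt, or a radial
vignette. Noise is additive Gaussian; images are rounded and clipped
to the bit depth. Ground truth (label map, centers, radii, exact mean
signal per bead) is emitted alongside every render.

`simulate_assay_series` builds a full bait × prey condition grid
(default 3 bait levels — 3/6/9 — by 4 prey levels over a 6-fold
range). Each bead carries a lognormal multiplier (mean 1, configurable
CV, default 15%) emulating bead-to-bead bait-density variation; lysate
and mock wells are rendered as small flat noisy fields such that mock
correction recovers the prey input.

Realism limits, by design: no optical point-spread function, no
Poisson photon statistics, no 3-D bead geometry, no phase-contrast
rendering, and bead intensity exactly linear in bait and prey inputs.
The generator validates the measurement pipeline's arithmetic and
segmentation behavior, not camera physics; conclusions about real
micrographs with heavy debris, out-of-focus beads, or nonlinear
detectors are out of its reach.

One internal-consistency note: with a zero background level, clipping
at zero truncates the negative half of the noise distribution and
shrinks the measurable background SD, so low-SNR regimes are rendered
with a background offset of several noise SDs (e.g. signal 200, noise
50, background 300 for the SNR-4 validation fields).

## Validation summary

Quantities computed by `scripts/acceptance.py --seed 1` on the
development machine (the script regenerates them from any seed):
mask recovery 0.998 over 1170 beads at SNR 4 with 0 false particles
and max matched-centroid error 1.99 px; background oracle deviation 0;
affinity-grid CV 0.027 over 12 conditions with minimum per-bait R²
0.9995; Welch/OLS oracle deviations < 4e-15; byte-identical reruns.

## Limitations

- Parameters are fixed-point conventions, not fitted to data; on real
  micrographs the area and circularity cuts, and especially the
  rolling-ball radius, may need retuning to magnification and bead
  size.
- The affinity model assumes linearity in bait and prey inputs and a
  linear camera; saturation handling only excludes or flags, it does
  not correct.
- Blank-bead autofluorescence is a single scalar per run, not a
  per-bead or spatially varying estimate.
- The watershed splits touching pairs reliably but chains or clumps of
  many beads are untested territory.
- The statistics module offers pairwise Welch tests without multiple-
  comparison correction; with a 12-condition grid, 66 pairwise p-values
  need external correction if used inferentially.
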