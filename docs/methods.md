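# Methods

This note documents the models, parameter choices and numerical
conventions behind `octarep`, and what the synthetic-data experiments do
and do not demonstrate.

## Problem setting

Widefield (15 × 9 mm²) swept-source OCT angiography produces en-face
angiograms of the superficial capillary plexus (SCP), deep capillary
plexus (DCP) and choriocapillaris (CC), sampled at 800 × 534 pixels. The
package quantifies each scan — perfusion density (PD) of large vessels and
of the full plexus under several vessel-enhancement filters, and CC
flow-void area/count/size under SD thresholding — splits every metric into
a fovea-centred 6 × 6-mm macular square versus the remaining periphery,
and assesses inter-visit repeatability over a two-visit cohort with paired
t-tests, ICC(2,1), Bland–Altman limits of agreement, and Pearson
correlation of filtered against unfiltered metrics.

## Coordinate and unit conventions

* Images are row-major 2-D arrays in [0, 1]; 0-based (row, col) indexing.
* The physical pixel pitch is carried per axis (nominally isotropic
  sampling of a 15 × 9-mm field at 800 × 534 px gives 18.750 µm/px in x
  but 16.854 µm/px in y; the exact quotients are used, never the nominal
  isotropy). Every physical parameter is named with its unit (`*_um`,
  `*_mm`).
* Masks are boolean arrays registered to the image grid.
* All filters use reflect padding; an image frame of zeros would otherwise
  masquerade as high-contrast ridge structure at the borders.

## Region partition

The macular region is the set of pixels whose integer centre coordinates
fall in the half-open rectangle `[fovea − 3 mm, fovea + 3 mm)` per axis;
the periphery is its complement. Half-open inclusion makes the partition
exact (disjoint and exhaustive) for every grid/pitch/centre combination —
at the default geometry the macula is exactly 320 × 356 px of the
427,200-px field. The fovea defaults to the geometric image centre
(widefield scans are fovea-centred) and can be overridden per image via
the manifest. The optic disc is excluded only from the choriocapillaris
analysis, where it is part of the analysable-region definition.

## Vessel-enhancement filters

**Hessian (Frangi-type) vesselness.** Scale-normalized second derivatives
(γ = 2) at `n_scales = 4` log-spaced scales spanning vessel diameters
15–44 µm, mapped to per-axis Gaussian sigmas σ = d/(4·pitch) (a Gaussian
ridge of width d peaks in |λ₂| near σ ≈ d/4). Per pixel and scale the
bright-ridge response is `exp(−R_b²/2β²)·(1 − exp(−S²/2c²))` with
β = 0.5, blobness R_b = λ₁/λ₂, structureness S the Hessian Frobenius
norm, and c set per scale to half the maximal S; dark ridges (λ₂ ≥ 0)
score zero, and the output is the maximum over scales. Discrete Gaussian
derivative kernels at sub-pixel sigma do not sum exactly to zero; each
scale's kernel DC is measured on an impulse and subtracted so a constant
image has an exactly-zero response (this also restores offset
invariance).

**Gabor bank.** 16 orientations stepped by π/16 spanning [0, π), real
zero-mean kernels with wavelength 20π ≈ 62.8 px, envelope σ = 0.56 ×
wavelength, aspect γ = 0.5, truncated at 2.5σ. The wavelength is treated
as a pixel quantity (it is dimensionally ambiguous in common usage;
configurable). The DC of each kernel is removed inside the envelope so
constant images give zero response. The output is the per-pixel maximum
over orientations (the standard choice for vessel enhancement), min-max
rescaled to [0, 1]. The bank is evaluated with one shared FFT of the
reflect-padded image.

**Bayesian residual denoising.** The image is decomposed into residuals
between successively smoother Gaussian scales (σ = 1, 2, 4 px plus a
coarse layer). Each residual layer is shrunk with the BayesShrink rule
t = σ_n²/σ_x, where the layer noise SD σ_n is either the user-supplied
image-domain noise SD propagated through the layer's effective filter
(its L2 norm, measured on an impulse) or a per-layer robust MAD estimate,
and σ_x² = max(var(layer) − σ_n², 0). Soft shrinkage is the default;
σ_n = 0 reproduces the input exactly. This is a denoising transform, not
a ridge detector: it preserves capillary detail while suppressing
speckle.

## Binarization and perfusion density

The all-vessel mask uses local adaptive thresholding: vessel iff
intensity strictly exceeds the local mean over a 1.25-mm window (the
window per axis is the nearest odd pixel count, 67 × 75 px at the default
pitch) plus an optional offset (default 0). Strict inequality sends ties
— in particular constant regions — to background. With offset 0 the rule
is invariant to positive affine intensity maps, so global gain/offset
drift between visits does not move PD by construction.

Large vessels are segmented from the SCP by combining a band-restricted
Hessian vesselness (diameters 30–200 µm) with a band-matched Gabor
response (wavelength ≈ twice the mid-band diameter in pixels) as their
**geometric mean**, thresholded at `c × mean(enhancement)` with c = 3.0,
and cleaned of components under 50 px. Two design points deserve
explanation: (i) the max-combination of the two filters was tried first
and proved unstable — the min-max-rescaled Gabor response has a nonzero
background floor and a halo of roughly half a wavelength around each
vessel, so at low vessel coverage the mean-derived threshold floods the
halo; the product form keeps the background near zero because the Hessian
term vanishes off-vessel while the Gabor term still gates on oriented
structure. (ii) c = 3.0 was calibrated on clean synthetic scenes for a
subset-biased detector: Dice ≥ 0.83 against the rasterized truth across
seeds with ≥ 99% of detected pixels within one dilation of the true
vessels. Both are configurable. The large-vessel mask is computed once
per eye from the SCP and reused for the CC exclusions.

PD is `100 × |vessel ∧ region ∧ ¬exclusions| / |region ∧ ¬exclusions|`;
an empty effective region is an error, never NaN.

## Choriocapillaris flow voids

The CC angiogram is inverted and thresholded at `mean + k·SD` of the
inverted intensities, with k = 1 and 1.25 the conventional settings. The
mean and population SD are global statistics over the analysable region
(field minus SCP large vessels minus the disc); computing them over the
whole image is available via configuration. Voids are labeled 8-connected
(4-connected optional) with `min_component_px = 1` by default; count and
mean size are sensitive to both, which is why they are exposed. Per
region: area % uses the region's analysable pixels as denominator; a
component is counted in the region holding the majority of its pixels
(ties to the macula, so border-straddling voids are never double
counted); mean size is total void area in µm² (pitch_x × pitch_y per
pixel) divided by the count, so size × count reproduces the total area
exactly. A constant image has SD 0 and yields zero voids by the strict >
rule.

On i.i.d. Gaussian intensities the detected area fraction must equal the
upper-tail probability 1 − Φ(k) (15.87% at k = 1, 10.56% at k = 1.25);
this closed-form calibration is asserted in the test suite.

## Repeatability statistics

* **Paired t**: classical dependent t with df = n − 1. Zero-variance
  differences are flagged degenerate with p = 1 rather than NaN.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — computed from the two-way ANOVA mean squares; a constant
  visit offset therefore lowers the ICC. The 95% CI uses the F-based
  method with Satterthwaite degrees of freedom. The implementation
  matches an independent from-definitions oracle to < 1e-10 and the
  ICC(A,1) row of `pingouin.intraclass_corr` to float precision
  (cross-checked in the tests). ICC(3,1) (consistency) is available.
  Bands: < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90] good, > 0.90
  excellent — exactly 0.90 is "good" under the strict reading of the
  "> 0.90 excellent" convention. A fully constant table takes the flagged
  convention ICC = 1, CI (1, 1).
* **Bland–Altman**: differences oriented visit1 − visit2 (recorded in the
  output), limits mean ± 1.96 × sample SD.
* **Pearson** between each filtered/thresholded variant and its reference
  variant (the unfiltered scan for PD, the k = 1 threshold for flow
  voids), computed on per-subject two-visit averages, with a Fisher-z CI.
* No multiple-testing adjustment is applied; the per-row p-values are
  reported as-is and should be read accordingly.

## Synthetic scenes

The generator supplies study-shaped inputs with exact ground truth; every
generator is a pure function of (spec, params, seed), split into named
substreams (anatomy / noise / visit / cohort) so the two visits of a pair
share one anatomy bit-for-bit.

* **Retinal slabs**: 4 large-vessel trees drawn as mean-reverting random
  walks entering from the left/right field edges (arcade-like), root
  widths 60–180 µm tapering to a 30-µm floor, sparse branching; coverage
  is ~5 ± 2% of the field, in the range of real large-vessel PD. The
  capillary bed is a correlated Gaussian field (correlation ≈ the 20-µm
  capillary width) thresholded at the quantile matching the requested
  coverage, so the realized density is exact up to quantization.
  Intensities: background 0.15, capillaries 0.55, large vessels 0.90;
  multiplicative radial vignetting (default 25% at the field corner);
  speckle as `img × (1 + N(0, σ)) + N(0, σ/2)` clipped to [0, 1] with
  σ = 0.05. The DCP variant has no large-vessel tree and a slightly
  denser capillary bed.
* **Choriocapillaris**: a correlated texture (mean 0.55, SD 0.08,
  correlation 30 µm) with dark elliptical voids (lognormal areas, mean
  1500 µm², aspect 0.5–1, random orientation) placed by dart throwing
  with a ≥ 2-px separation until the requested fraction (default 0.12) is
  rasterized; the separation is relaxed in stages if a target approaches
  the packing limit. Void edges are softened (Gaussian σ 0.8 px) so a
  higher threshold genuinely erodes voids — this is what makes area,
  count and mean size all decrease from k = 1 to k = 1.25, the behaviour
  reported for real scans.
* **Visit pairs**: shared anatomy; visit 2 re-samples the speckle, applies
  a global gain `1 + N(0, within_subject_sd)` and optionally a sub-pixel
  translation. With zero SD and a shared noise stream the visits are
  identical.
* **Cohorts**: subject effects b_i ~ N(0, b) on the latent density target
  and visit effects w_ij ~ N(0, w) as gain perturbations; the implied
  true ICC of the latent metric is b²/(b² + w²). Defaults n = 14
  subjects, 2 visits, b = 0.03, w = 0.01 (density-fraction units).

What the synthetic data does **not** emulate: physical OCT speckle
statistics, flow decorrelation, projection artefacts, segmentation errors,
eye motion, or the anatomy of a real arcade/FAZ. Consequently, passing
tests demonstrate that the measurement and statistics machinery is
correct and calibrated — not that the specific ICC values generalize to
patient scans. One deliberate consequence: because adaptive local-mean
thresholding is affine-invariant, the visit-level gain perturbation
barely moves the retinal PD, so image-cohort ICCs run near 1; the
parameter-recovery experiments therefore operate on the latent cohort
values, where the true ICC is known exactly.

## Problem sizes used in the packaged experiments

Scenes are full-size (800 × 534) wherever a result depends on the
geometry; the flow-void monotonicity sweep uses 50 half-size
(400 × 268) scenes at the standard pitch, a size chosen to keep the sweep
brisk while leaving thousands of voids per scene; ICC recovery uses 200
replicate 14-subject cohorts; the end-to-end determinism check runs the
complete 14-subject, 3-slab, 2-visit pipeline twice.

## Known limitations

* The Bayesian residual filter is a concrete reconstruction of a
  published idea whose reference implementation is not public; it is
  labeled "modified" and its internals (residual pyramid + BayesShrink)
  are documented here rather than claimed to replicate the original.
* The Gabor wavelength convention (pixels) is an interpretation; other
  readings (µm) change the capillary response substantially and can be
  set via `GaborParams`.
* Flow-void counts depend on connectivity and minimum component size;
  comparisons across configurations are not meaningful.
* The generator's cohort visit effect acts through a global gain; metrics
  that are gain-invariant by design (adaptive-threshold PD) show
  near-perfect image-cohort repeatability, which is a property of the
  simulation, not a claim about device repeatability.
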