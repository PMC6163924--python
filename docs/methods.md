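# Methods

This note documents the models behind `earlyvigor`, the parameters that
matter, the design choices made where several readings were defensible,
and what the synthetic data do and do not establish.

## Sensing models

### Canopy cover from RGB images

A pixel is vegetation iff its hue lies in a window, saturation ≥ a floor
and value ≥ a floor, in hexcone HSV space (hue in degrees, hue set to 0
for achromatic pixels). Canopy cover is exactly
`n_vegetation_pixels / n_total_pixels`. Defaults: hue ∈ [60°, 180°],
`sat_min = 0.15`, `val_min = 0.05`. No published threshold values exist
for this workflow — practitioners adapt them per acquisition day on a few
images and freeze them — so the defaults are a generous green window that
excludes brown soil, and `calibrate_thresholds` formalizes the manual
step as a grid search maximizing mean pixel-wise Jaccard overlap with
reference masks (ties resolved toward the more inclusive setting: lower
saturation floor, wider window, lower hue minimum). Quadrat cropping is a
bounding-box crop of four corner points, not a perspective rectification:
quadrat photographs are taken near nadir and the reference workflow
cropped rectangles manually. Morphological cleanup is off by default (an
optional minimum-component-size filter exists for real photographs).

### Vegetation indices

Spectra live on a strictly increasing grid (nominally 3.3 nm over
300–1140 nm). Nominal index bands resolve to the *nearest* grid
wavelength, ties toward the lower wavelength, with no interpolation —
the convention for narrow-band indices from diode-array spectrometers.
The nine index equations are transcribed literally; two readings needed
fixing:

- REIP uses the four-point linear-interpolation form
  `700 + 40·(((R668+R778)/2 − R698)/(R738 − R698))`; the common inline
  typography of this equation is ambiguous about precedence, the cited
  original form is not.
- ATSAVI keeps the printed adjustment constants 1.22 / 0.03 / 0.23
  exactly (they are standard, not site-calibrated).

Zero denominators (e.g. REIP or MTCI on a spectrum flat across the red
edge) raise a typed error carrying the index name; table builders record
such cells as missing with reason `zero_denominator`, never silently.

The active-sensor NDVI emulation averages reflectance over unweighted
boxcar windows 656 ± 12.5 nm (red) and 774 ± 12.5 nm (NIR); the true
diode response function of such sensors is unpublished, so a flat window
of the stated ~25 nm width is the neutral choice.

### Spectral unmixing

The mixed spectrum is regressed by OLS on the soil and vegetation
endmember spectra, *without intercept* and with unconstrained
coefficients; cover is `b_veg/(b_veg + b_soil)`. Rationale: the
coefficient-ratio estimator only makes sense if the endmembers themselves
absorb the full signal — an intercept would soak up part of the soil
fraction ambiguously. The intercept is exposed as an option for
sensitivity analysis. Bands below 400 nm are excluded by default
(scattering); endmember pairs with design condition number above 1e8 are
rejected as degenerate. With noiseless linear mixtures the estimator is
exact for any cover in [0, 1]; it is equivariant to a common positive
rescaling of all three spectra, and swapping the endmember roles maps
cover c to 1 − c. A brightness-mismatched soil endmember biases sparse
canopies much more in relative terms (~28% at cover 0.05 for a 1.3×
bright soil) than near-closed ones (~4% at 0.84); in absolute terms the
bias is largest at high cover — the early-season problem is a
relative-error problem.

### Contour-map screening

For all band pairs ≥ 400 nm, the per-plot normalized difference index is
correlated with the trait; entries are squared Pearson correlations.
Only the upper triangle is computed (the matrix is symmetric); the full
matrix is materialized for plotting. Undefined entries (zero band sums,
constant indices, < 3 valid plots) stay undefined and are excluded
pairwise-complete from the across-date mean and CV and from the argmax —
never imputed as zero. The CV uses the sample (n−1) standard deviation;
this is the convention that reproduces the published aggregate cells
(e.g. per-date values 0.45/0.53/0.55/0.45 give CV 0.11 with the sample
SD but 0.09 with the population SD). The argmax of the mean matrix
breaks ties toward the pair with the smaller band separation, then the
lower wavelength — unspecified in the source, fixed here for
determinism. Band groups: VIS 400–680 nm, red edge 680–740 nm, NIR
740–1140 nm, boundaries belonging to the lower-named group.

### Evaluation and the summary table

Correlation cells are squared Pearson r with a two-sided p from the
t transform at n−2 df; stars are `*`/`**`/`***` at strict p < 0.05 /
0.01 / 0.001. No multiple-testing correction is applied anywhere — the
screening is exploratory and the reference analysis applied none.
Across-date mean and CV include non-significant values at their raw
magnitude; rows with genuinely missing dates get no mean/CV (the
unpublished raw values behind blank cells cannot be reconstructed).

Display rounding is half-up to 2 decimals. The contour-gain ratio rows
use two deliberate policies, both implemented and labeled: per-date
cells divide the 2-dp contour maximum by the best competing 2-dp cell
(this reproduces the published date cells, e.g. 0.42/0.31 → 1.35), while
the mean-column cells divide by the best *unrounded* competing mean
(0.67/0.605 → 1.11). "Best established sensor method" scans every method
except the contour map; "best established hyperspectral vegetation
index" scans only the nine indices. Two published date-2 sensor-ratio
cells do not follow this (or any single) consistent rule and are flagged
as such in `earlyvigor.datasets`.

## The synthetic trial generator

The generator's job is to produce data with the statistical structure the
analysis assumes, with known ground truth, so that every downstream stage
is testable without field data.

**Design.** Four dates (growth stages seedling to early stem elongation),
36 plots per date from 2 N levels × 3 sowing densities × 2 cultivars × 3
replicates. Treatment factors carry labels but no fixed effect by
default: at these early stages the reference trial found mostly no
significant treatment effects, and plot-to-plot heterogeneity dominated.
All variation is a per-plot random effect.

**Traits.** Date means: DW (73, 213, 621, 1812) kg ha⁻¹ (the endpoints
are the reported trial averages, the interior points geometric — i.e.
exponential growth); NC (5.0, 5.0, 5.0, 4.6)%; CC (0.045, 0.18, 0.50,
0.84) — sigmoidal from 4.5% to 84% cover. DW plot effects are log-normal
with log-sd `plot_cv` (default 0.25; keeps DW positive and the mean
exact after the −σ²/2 correction). NC deviations are Gaussian
(sd 1.6·`plot_cv` percentage points), truncated to [2, 7]%, and on dates
3–4 correlated with the DW effect at `nc_dw_tradeoff` (default −0.6),
reproducing the late dilution trade-off; on dates 1–2 NC is independent
of DW. Nup is *always* computed as DW·NC/100. Cover is a logistic
function of log DW with slope 1.6 and saturation 1, plus logit-scale
jitter (sd 0.72·`plot_cv`); the date-specific midpoint is solved by
Brent's method on the realized draws so the sample mean cover equals the
design mean exactly. Setting `plot_cv = 0` therefore collapses every
plot at a date onto the date means. The dispersion defaults were chosen
so that per-date CC–DW correlations land in the R² ≈ 0.75–0.85 band the
reference trial reported, not to reproduce any specific table cell.

**Spectra.** Each plot's spectrum is the exact linear mixture
`cover·vegetation + (1−cover)·soil` plus zero-mean Gaussian noise
(default sd 0.005 reflectance units), with bands above 1000 nm receiving
`nir_noise_boost` × that sd — default 4× on date 1 and 1× later,
emulating the stronger early-season scattering in the high NIR. The 4×
magnitude is a package choice (no measured value exists); it is large
enough that NIR/NIR normalized-difference pairs visibly lose temporal
stability, as observed in the field. Values are clipped to [0, 1]. The
default endmembers are parametric curves — a brown soil ramp
(0.10 → 0.32) and a vegetation spectrum with green bump, chlorophyll
trough, sigmoidal red edge to a ~0.47 NIR plateau and a water dip near
975 nm. They are qualitatively realistic shapes, not measurements; all
recovery tests need is a well-conditioned, red-edged pair.

**Images.** Vegetation is painted as elongated organic patches: an
anisotropically Gaussian-smoothed random field thresholded at the exact
pixel count nearest the target cover, so the returned `true_cover` is the
exact green fraction by construction (within one pixel of the target).
Vegetation pixels get hues 95–140°, saturation 0.45–0.90 and brightness
jitter 0.35–0.85; soil is a brown speckle (hues 18–42°). The default
size is 600 × 600 px (a parameter): large enough for < 0.02 granularity
and fast enough for batch tests; full-resolution field photographs
(~2400²) add nothing to the logic being tested.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: no radiative transfer, BRDF, sun-angle
or shadow effects; no 3-D canopy structure (cover and biomass are linked
by a fixed monotone law, whereas real canopies decouple when growth turns
vertical); no soil moisture or roughness dynamics beyond the date-1 noise
boost; no specular highlights, mixed pixels or JPEG artifacts in the
rendered images (segmentation accuracy on renders is a consistency check,
not a field-accuracy claim); endmembers are known exactly, so unmixing
recovery rates here are upper bounds on field performance, where manual
endmember selection is a major error source.

## Numerical choices

- Nearest-band lookup tolerance is implicit (half the local grid step);
  ties go to the lower wavelength.
- Pairwise R² columns are computed from one-pass sums with NaN masking;
  variances below 1e−18·n are treated as zero (constant index).
- Half-up display rounding adds a 1e−9 guard so that binary-float
  representations of exact halves (0.605 stored as 0.60499…) round up as
  intended.
- `brentq` midpoint solving brackets ±40 on the log-DW axis, ample for
  any cover target in (0, 1).
- Sub-seeds for independent experiment arms come from
  `numpy.random.SeedSequence` spawning/state, keeping every derived seed
  below 2³¹.

## Problem sizes used in validation

The validation suite runs: 1000 Monte-Carlo unmixing draws at cover 0.3,
noise sd 0.005 (within ±0.02 in ≥ 95% of draws; the observed estimator
sd is ≈ 0.003); 50 rendered 600² images spanning cover 0.02–0.95
(mean absolute segmentation error < 0.02); 10⁴ null replicates at n = 36
for the correlation test (rejection rate 5% ± 0.6%); 100 independent
single-date seedling-stage trials of 36 plots with 160² images for the
method-ranking pattern; and a 10-band × 20-plot × 3-date brute-force
oracle for the screening pipeline (agreement to 1e−12). These sizes give
comfortable statistical margins while keeping the full suite around a
minute of compute.

## Known limitations

- The published table's two date-2 sensor-gain cells and the N-content
  mean-column gain cannot be reproduced from printed values (see
  `earlyvigor.datasets` flags); they are excluded from arithmetic checks.
- Unmixing offers no constrained (non-negative / sum-to-one) variant and
  no automated endmember extraction.
- The screening considers two-band normalized differences only; no
  three-band indices, no cross-validation of the selected pair — the
  mean/CV aggregation is descriptive, and the selected "best" pair is
  optimistically biased like any in-sample maximum.
- Threshold calibration searches a fixed modest grid; it is a surrogate
  for, not an improvement on, expert manual tuning.
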