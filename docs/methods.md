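# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic experiments do and do not demonstrate.

## Radiometric calibration

Digital numbers are converted to surface reflectance with a single-point
empirical line through the origin: per band,
`reflectance = (DN − dark) / (DN_panel − dark) × ρ_panel`, where
`DN_panel` is the mean DN over a grey reference panel and `ρ_panel` its
known reflectance (for the six-band camera: 7.008, 7.291, 7.239, 7.442,
7.667 and 8.433 % at 450–850 nm). A through-origin line is the standard
single-panel convention; a two-point line would need a second panel. The
optional per-band dark offset defaults to 0.

## Background masking

A pixel is classified wheat iff it is valid and strictly exceeds both a
green-band reflectance threshold (R₅₃₀ > 0.063) and a VARI threshold
(VARI > 0.08), with VARI = (R₅₃₀ − R₆₇₅)/(R₅₃₀ + R₆₇₅ − R₄₅₀). The two
criteria are combined with AND by default (OR is available as a config
switch); pixels exactly at a threshold are background, and zero-denominator
VARI pixels are missing, hence background. Thresholds are per-scene
parameters because canopy brightness drifts across acquisition dates; the
defaults suit a reflectance-calibrated scene whose soil line sits below
R₅₃₀ ≈ 0.06.

## Zonal statistics

Plot summaries are arithmetic means over pixels whose *centres* fall
strictly inside the ROI polygon and that are valid (and green, for
green-pixel statistics). Centres exactly on the polygon boundary do not
contribute; this is a measure-zero convention that keeps results identical
under vertex reordering and joint translation. Spectral indices are
computed from the zonal mean reflectance (index of means), not pixelwise.

## GLCM texture engine

Per band, the scene is min–max quantized to 64 gray levels over the
eligible pixels of the *whole* orthomosaic (global quantization, so
neighbouring windows share one gray scale; an optional percentile clip
guards outliers, default off). A 3×3 window slides over every pixel whose
window fits inside the raster — border pixels of half-window width are
missing rather than padded, since padding would fabricate texture. Within
a window, pixel pairs at the 45° offset (Δrow, Δcol) = (−1, +1) at
distance 1 are accumulated symmetrically and normalized, and the eight
features (MEA, VAR, HOM, CON, DIS, ENT, SEM, COR) are evaluated with the
standard Haralick/Conners definitions stated in `spsi.texture`. MEA and
VAR are in quantized-level units (0–63), by GLCM convention.

In green-pixel mode, background pixels are excluded both from the
quantization statistics and from co-occurrence: a pair counts only if both
pixels are green. This avoids fabricating soil–canopy contrast at row
edges. Windows with no countable pair yield missing texture and are
excluded from zonal means. COR is missing where a marginal variance
vanishes (uniform window); the degeneracy test uses an absolute product
threshold of 1e−20, which separates exact-uniform windows from rounding
noise at 64 levels.

The sliding evaluation is algebraically identical to building each
window's co-occurrence matrix but is vectorized over centres: each centre
owns at most (w−|Δr|)(w−|Δc|) pair origins, gathered as shifted slices,
and cell-level sums (ENT, SEM) use duplicate counting over those few
entries. The test suite verifies exact agreement (1e−10) with a
brute-force pair-enumeration oracle on masked random images, and checks
the single-window path against scikit-image's `graycomatrix` (whose π/4
angle is the symmetric equivalent of our 45° convention with rows counted
downward).

## Composite index and band search

Textural indices substitute per-band zonal texture means into spectral
index formulas; NDTI_COR(λ₁, λ₂) is the normalized difference of the COR
feature of two bands. The exhaustive search regresses the trait on
NDTI_COR for every ordered band pair (30 pairs for six bands), records R²
and the correlation sign, and returns the strongest positive and negative
pairs (ties broken toward shorter wavelengths; by the antisymmetry of the
normalized difference the two are transposes of each other). SPSI is the
exact, unweighted sum of the chosen spectral index and NDTI_COR; a
pipeline-level check confirms the two components correlate with the trait
with the same sign before they are summed. The search keeps all pairs; any
display cutoff is a plotting concern, not part of the method.

## Modelling and metrics

The trait is regressed on one index at a time by ordinary least squares.
Data are split once into calibration and validation by a stratified random
draw within each dataset label, round-half-up(fraction·n) per stratum
(2/3 of 48 and 81 plots gives 32 + 54 calibration, 16 + 27 validation),
deterministic given the seed. Calibration R² is the squared Pearson
correlation. Validation is scored about the 1:1 line:
R²_V = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², which can be negative (worse than predicting
the mean) and is then reported as 0; RMSE = √(Σ(y−ŷ)²/n) in trait units;
RRMSE = RMSE/ȳ × 100. ȳ is the mean measured trait of the samples being
evaluated (a calibration-mean centre is available as an option). If the
validation trait has zero variance, R²_V is undefined and reported
missing, not clamped. Plots with missing index values are dropped
pairwise per index.

## Synthetic study conditions

The generator emulates a two-experiment campaign: 48 plots (multi-cultivar
style, "VE") and 81 plots (multi-density style, "SE"), sharing spectra and
a latent plant-density range of 100–900 plants/m². Its components:

- **Trait.** PNPA = 270·ln(density) − 1050 + N(0, 35), spanning roughly
  200–800 ×10⁴/ha — the logarithmic tiller-to-panicle link at a realistic
  field scale.
- **Canopy geometry.** North–south row stripes with period 5 px; cover
  rises from ~0.5 to ~0.9 with density and is realized by cumulative
  (Bresenham) rounding of stripe widths, so realized cover tracks the
  target within half a column and the mask-recovery check (±0.05) is
  meaningful.
- **Spectra.** Canopy reflectance follows a response curve u(density)
  that is linear up to a knee (400 plants/m²) and exponentially flattens
  above it; the NIR band carries most of the response. This makes
  red-edge/NIR indices saturate: the fitted DATT-vs-density slope above
  the knee is ≥5× smaller than below. Plot-level jitter on u and
  independent 730/850 nm offsets play the role of cultivar and nitrogen
  effects. Soil is set so the default masking thresholds separate it from
  canopy.
- **Texture.** Within-canopy fluctuations mix an oriented component —
  constant along up-right diagonals within 8-row bands, i.e. correlated
  exactly at the 45° GLCM offset with no long-range order — with white
  noise. The NIR mixing weight rises with log-density (gain 0.13 from a
  0.84 base); the red-edge weight is fixed at 0.93; visible-band weights
  carry large plot-level jitter unrelated to density. Zonal COR therefore
  keeps discriminating density after the spectral signal flattens, the
  (850, 730) pair is the planted optimum of the band search, and pairs
  involving visible bands are noisy also-rans. Weights stay above ~0.6 so
  zonal COR remains positive scene-wide: the 3×3-window estimator carries
  a negative small-sample offset, and NDTI_COR needs denominators away
  from zero to be stable. Oriented fields and their realized variances
  are independent and standardized per plot, so plot-level texture errors
  are uncorrelated.
- **Pooled-data stratification.** The SE scene includes a field-margin
  vegetation strip outside every ROI whose 730 nm values span 0.30–0.80.
  It stretches that scene's global quantization range, which rescales and
  offsets level-based texture features (MEA, VAR) for every SE plot while
  leaving zonal reflectance and the scale-free COR feature untouched —
  reproducing how texture *levels* stratify across independently
  quantized campaigns while COR-based indices do not.

Stratification is measured on the pooled samples: the R² advantage of
per-dataset regression lines (combined SSE over pooled SST) over the
single pooled line. Compared with differencing per-dataset R² values,
this cancels the sampling noise of R² estimates at n = 48 per stratum
(±0.06 under the null) and isolates the structural offset.

What the passing tests show: the pipeline's algebra and texture engine
are exact; and *given* a saturating spectral response plus an oriented,
density-tracking texture signal, the method's selection and composition
steps behave as designed (the search finds the informative pair, the
composite beats both components, level-based texture stratifies across
scenes while correlation-based texture does not). What they do not show:
that real wheat canopies exhibit texture of this form or strength — the
generator plants ideal oblique micro-structure, contains no weeds, shadow
classes, view-angle or illumination gradients, no geometric or
co-registration error, and one date rather than a phenological series.
Absolute R² values on synthetic data say nothing about field accuracy.

## Numerical conventions

Missing values are NaN end to end; zero denominators never produce
infinities. Quantization uses floor((x−min)/(max−min)·levels) clamped to
levels−1, constant images map to level 0. The random band-pair search
breaks exact R² ties (within 1e−15) toward the lexicographically smallest
wavelength pair. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; scenes, splits and pipeline outputs are
bit-reproducible given the seed. Problem sizes in tests (24×32-pixel
plots, 50-seed replicate sweeps, 8×8 oracle images) were chosen as the
smallest at which the estimators' behaviour is stable.

## Known limitations

The raster layer reads multi-band TIFFs with a JSON sidecar for
wavelengths and the affine transform; GeoTIFF tags of third-party mosaics
are not parsed — supply wavelengths explicitly for foreign files. The
GLCM engine fixes the offset set to the four canonical angles at integer
distances. The 3×3 masked COR estimator is biased low in narrow canopy
stripes; zonal means inherit a cover-dependent component that real
analyses should treat as part of the signal model, as done here.
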