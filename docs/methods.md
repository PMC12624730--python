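# Methods

This note documents the models, conventions and numerical choices behind
`aquarad`, what the synthetic campaign generator does and does not emulate,
and the known limitations.

## Spectral model and grid

All analysis happens on a uniform, closed wavelength grid, by default
390–880 nm at 1 nm (491 points, both endpoints included). That window is the
overlap of a typical low-cost device (≈ 313–889 nm) with a reference
spectroradiometer (≈ 331–2500 nm) and the range conventional for aquatic
remote sensing; spectrometer edge regions outside it have low SNR and are
excluded rather than down-weighted.

Resampling is piecewise **linear only** — no splines, no smoothing — and
never extrapolates: a grid outside a spectrum's support raises an error
rather than producing NaN fills, because edge effects are a known artifact
region and silent fills would leak into calibration fits. Masks (saturation,
invalid samples) propagate *pessimistically*: an output sample is masked as
soon as its two-point interpolation stencil touches a masked input sample; a
grid point coinciding exactly with an input sample inherits only that
sample's mask. How field campaigns handle invalid samples during
interpolation is rarely documented; pessimism is this package's choice
because the cost of a falsely valid sample (a saturated count biasing a
regression) far exceeds the cost of a falsely masked one.

## Radiometric calibration

The device's factory wavelength solution is a degree-5 polynomial in pixel
index (six coefficients, 288 pixels by default, both configurable); it must
be strictly increasing over the pixel range. Pixels at or above the
saturation ceiling (default 65535, the 16-bit limit) are masked at this
stage and can never enter a fit — verified by a test that injects a clipped
value which would otherwise shift the slope.

Calibration is fit **in the wavelength domain** after resampling both
instruments to the analysis grid, not in pixel space, because the two
instruments only become comparable on a common grid. At each grid wavelength
independently, ordinary least squares of reference radiance on device counts
across stations gives gain (radiance per AU) and offset (radiance), plus the
squared Pearson correlation of the fit. Full OLS with an intercept is used
rather than a forced-through-origin fit: dark current and stray light give
the device a genuine nonzero response at zero radiance, and reported bias
metrics presuppose an offset term. The per-column OLS is implemented in
closed form (slope = S_xy/S_xx) and checked in tests against
`scipy.stats.linregress` to machine precision. Wavelengths with fewer than
two usable (unmasked) pairs, or zero count variance, are masked in the
output calibration.

Two optional corrections are off by default because neither is part of the
core linear model: subtraction of a stored dark counts spectrum before
fitting, and linear rescaling of counts to a common integration time when
integration times differ within one fit (linear-detector assumption).

Transferability is assessed by **leave-one-location-out** cross-validation:
for each site, all three component calibrations are fit on every other
site's stations and applied to the held-out site; agreement is reported for
each radiance component and for the derived R_rs, pooling the held-out
site's stations and unmasked wavelengths.

## Reflectance equation

R_rs(λ) = (L_w − ρ·L_sky) · R_ref / (π · c_panel · L_c)

with defaults ρ = 0.02 (fixed scalar sky-glint factor for the 40° zenith /
135° azimuth viewing geometry), R_ref = 0.99 (white Spectralon panel) and
c_panel = 1.01 (panel non-ideality). The grouping reads the panel term as an
irradiance estimate E_d = π·c_panel·L_c/R_ref; whether the 1.01 factor
multiplies or divides L_c is not settled by every protocol write-up, so the
factor is an explicit, configurable parameter and the chosen grouping is the
one consistent with the panel-to-irradiance reading. ρ is deliberately a
scalar — wind- and geometry-dependent glint tables are out of scope.
Wavelengths with L_c ≤ 0 are masked (no usable irradiance information).
`invert_rrs` is the exact algebraic inverse and is what the synthetic
forward model uses.

## Satellite band simulation

A band value is ∫RSR·R_rs dλ / ∫RSR dλ over the band's support. Both the
RSR table and the spectrum are piecewise linear, so their product is
piecewise quadratic on the union of the two sample grids; the numerator is
integrated with the exact closed form per interval (equivalent to Simpson
after midpoint refinement) and the denominator with the trapezoid rule,
which is exact for a piecewise-linear integrand. This makes the quadrature
exact for the interpolation model — tests confirm ≤ 1e-6 relative agreement
against a 10×-dense independent quadrature and exact constant-spectrum
normalisation.

Built-in band sets are Gaussian approximations from public center/FWHM
documentation (5 nm FWHM for the hyperspectral ocean-color sensor's
560/620/665/681/708 nm channels; OLCI Oa06–Oa11 at nominal centers 560,
620, 665, 681.25, 708.75 nm with 10/10/10/7.5/10 nm FWHM), sampled
symmetrically about the center at 0.25 nm out to ±4σ. Official tabulated
RSRs can be loaded from files and take precedence. The 590–610 nm region
some providers exclude for the hyperspectral sensor is carried as advisory
band-set metadata, not a hard removal.

## Bloom indices

All four indices are built from three primitives with configurable band
roles and signs; wavelengths entering baseline terms are the *matched
bands' actual centers* (e.g. 681.25 nm for OLCI Oa10), matched to the
requested nominal center within 3 nm.

- NDCI = (R708 − R665)/(R708 + R665), in [−1, 1] for positive bands.
- PC3 = sign·(1/R620 − 1/R665)·R708, **default sign −1** so that deeper
  phycocyanin absorption at 620 nm gives *lower* PC3, matching the
  direction reported for this index alongside rising NDCI/CI/PCI in bloom
  comparisons. The published raw form is recovered with sign +1. Note the
  *value's* sign at any one station depends on the baseline slope between
  620 and 665 nm; only the direction of response to phycocyanin is fixed.
- CI = −SS(681; 665, 708) and PCI = −SS(620; 560, 665), where SS is the
  baseline-subtracted band height; the −1 signs make a deeper
  trough/absorption dip produce a larger index.

Undefined values (zero denominators, masked or missing bands) propagate as
NaN with a warning — one bad band never fails the other indices. An
optional per-index vicarious recalibration (OLS slope/offset against a
reference index series) is provided but off by default, since such
procedures are campaign-specific.

## Agreement metrics

Magnitude metrics treat the second argument as reference and are
deliberately asymmetric: R² is squared Pearson correlation (a separate bias
metric makes regression-through-origin R² redundant); %NRMSE normalises
RMSE by the reference **range** (max − min), with mean-normalisation behind
a flag; MAPE is the plain arithmetic form over nonzero references; β is the
signed symmetric percentage bias 100·sign(Z)·(10^|Z| − 1) with Z the median
of log10(est/ref) over strictly positive pairs, so estimate = 2·reference
gives exactly +100 %.

Shape metrics: SAM is computed in the chord form 2·arcsin(‖u − v‖/2) on
unit vectors — algebraically the spectral angle, but exactly zero for
identical inputs and stable for near-parallel spectra, where the arccos
form loses half the significand. SID symmetrises the KL divergence between
the spectra normalised to unit sum after clipping to ε = 10⁻⁸ (R_rs can
touch zero at the red/NIR edges); SED is the plain Euclidean distance and
intentionally scale-dependent. Per-wavelength profiles apply the magnitude
metrics independently at each wavelength across a stack of station pairs.

## Synthetic campaign generator

The generator exists to test the chain, not to model radiative transfer.

- **Scene**: R_rs = baseline − pc·0.35·b·G(620, 15 nm) − chl·0.35·b·G(665,
  15 nm) + chl·0.50·b·G(708, 12 nm), where b is the backscatter level
  (default 0.01 sr⁻¹, a turbid inland-water magnitude) and G a Gaussian.
  The baseline b·(0.25 + 0.9·logistic decline centered at 645 nm, width
  60 nm) is green-high/NIR-low and nearly linear across 560–665 nm, so a
  no-bloom scene yields near-zero baseline-subtraction indices. A seeded
  sum of three low-frequency cosines (≲ 1 % of baseline) differentiates
  stations without breaking positivity or the strict monotonicity of each
  index in its pigment parameter.
- **Environment**: sky radiance is a Rayleigh-like (400/λ)⁴ curve over a
  floor; panel radiance a broad solar-like hump; both scaled by a
  per-station brightness factor (default draw 0.7–1.3) representing
  illumination variability. Positivity and smoothness are all that matters
  here; these are not physical sky models.
- **Instrument**: counts = (radiance − offset)/gain + dark, with smooth
  wavelength-dependent true gain (≈ 10⁻³ radiance/AU) and offset, dark =
  120 AU, multiplicative Gaussian noise (default σ = 1 % of signal), and
  clipping at the saturation ceiling with masking. Noise is multiplicative
  only; Poisson shot noise is out of scope.
- **Ground truth convention**: the reference instrument reports the exact
  linear radiometric model applied to the piecewise-linear interpolant of
  the device's noiseless pixel-sampled counts. Both instruments thus
  observe the same band-limited field, which makes the zero-noise chain an
  exact identity (held-out R² = 1, %NRMSE = 0 to machine precision) and
  lets tests attribute any error to estimation rather than sampling
  mismatch. Consequently the generator does **not** emulate real
  instrument-pair bandwidth/sampling differences, wavelength-registration
  errors, temperature-dependent dark drift, or bidirectional reflectance
  effects — passing tests say the estimators are correct, not that a real
  device pair would achieve these numbers.
- **Campaign**: default 31 stations over 6 sites (6/5/5/5/5/5); each site
  draws its own chlorophyll and phycocyanin levels, stations jitter them
  slightly. Everything is driven by one integer seed; identical seeds give
  bit-identical campaigns.

## Verification problem sizes

The verification script (`scripts/acceptance.py`) uses: one noiseless
6-site/31-station campaign for the leave-one-location-out identity; 100
replicate noisy campaigns for gain recovery; 10 randomized triplets for the
reflectance oracle; all 10 built-in bands against 10×-dense quadrature;
10-point parameter sweeps for index monotonicity; 60-sample vectors for the
metric fixed points; and paired 3-site campaigns for determinism. These
sizes give stable statistics in seconds on one CPU.

## Numerical conventions and degenerate inputs

All file artifacts serialise floats with 17 significant digits, so runs
round-trip bit-exactly and identical seeds give byte-identical artifacts.
Degenerate situations are errors when the caller must decide (fewer than
two usable samples, no wavelength fit at all, non-monotone wavelength
polynomial, unit mixing, grid mismatch) and NaN-with-mask when a value is
locally undefined inside an otherwise valid computation (zero index
denominators, degenerate reference range in NRMSE, no positive pairs
for β).

## Known limitations

- The linear radiometric model has no temperature term; dark-current drift
  shows up as calibration bias, as it would on a real device.
- Built-in Gaussian RSRs approximate real sensor responses; use official
  tables for real match-up work.
- Index values are unitless proxies; conversion to pigment concentrations,
  toxicity inference and bloom classification are out of scope, as are
  atmospheric correction and satellite granule ingestion.
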