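# Methods

## Spectral model

The camera samples tissue reflectance through B Gaussian band-pass filters
(default B = 8). A filter is parameterised by centre wavelength, FWHM and
peak transmission, with transmission

T(λ) = T_peak · exp(−4·ln2·(λ−λ_c)² / FWHM²).

Because the white-reference normalisation cancels the illuminant spectrum
and every wavelength-independent throughput factor, only the passband
*shape* matters downstream. The band value of any wavelength-resolved
quantity S(λ) is therefore its transmission-weighted mean,

S_b = ∫ S(λ) T_b(λ) dλ / ∫ T_b(λ) dλ,

evaluated by composite-trapezoid quadrature on the spectrum's grid. The
trapezoid endpoint weights matter at the grid edges: the default extinction
grid spans 450–650 nm while the outermost filters sit at 470 and 645 nm, so
their tails are truncated by the grid and a plain rectangle sum would carry
a first-order edge error. With trapezoid weights the quadrature is
second-order in the grid step; at the packaged 0.25 nm step it agrees with a
0.1 nm brute-force reference to ~10⁻⁴ relative even in the dimmest band.
(An earlier 1 nm tabulation left ~10⁻³-level discretisation error against
the fine-grid reference at the 600 nm band, where the sharp 577 nm
oxyhaemoglobin feature meets a small absolute value; 0.25 nm was adopted for
that reason.) A grid that captures less than half of a filter's analytic
passband weight is rejected as not covering the passband.

### Extinction data

The packaged extinction tables (`*_extinction_synthetic.tsv`) are smooth
analytic approximations, built from sums of Gaussians, of the visible-band
spectra of oxyhaemoglobin (α/β bands at 577/542 nm plus a blue-rising
Soret-tail term), deoxyhaemoglobin (broad 556 nm band), and white adipose
tissue (carotenoid-type blue absorption that renders fat visibly yellow).
They are in relative units on a common scale — concentrations recovered
against them are relative, not molar — and are deliberately synthetic:
they reproduce the feature positions and contrast that make the four-column
design matrix well conditioned (condition number ≈ 46 for the default
bank), not any particular laboratory compilation. Users with calibrated
extinction tables can substitute them as TSV files.

### Filter bank

Default octet: 470, 500, 520, 546, 560, 577, 600, 645 nm, FWHM 20 nm, peak
0.9. The centres straddle the oxy/deoxy difference features (546/560/577)
and add blue, green and red anchor bands; the set is a stand-in for
whatever physical wheel is in use and is fully overridable via a YAML
config (`load_filter_bank`).

## Calibration

Reflectance is computed per pixel per band as
R = (I_raw − I_dark)/(I_white − I_dark). Numerical guards, all
configurable:

- denominator floor ε_denom = 1 count — pixels whose white-minus-dark
  signal falls at or below it are flagged invalid rather than divided;
- saturation — pixels at the sensor's full scale (default 4095, a 12-bit
  sensor) are flagged invalid, since a clipped numerator silently biases R;
- reflectance floor r_floor = 10⁻⁴ before the log, bounding absorbance at
  4 so A = −log₁₀ R is finite everywhere.

The white reference is treated as an ideal uniform reflector; correction is
per pixel (strictly more general than per-band means, and identical for a
spatially uniform white stack).

## Unmixing

Per pixel, ordinary unconstrained least squares of the B-vector of
absorbances on the B×4 design matrix (band-convolved ε for HbO₂, Hb, fat,
plus a ones column for the scattering offset G). The fit is vectorised over
all pixels with a single `lstsq` call. CoD = 1 − SS_res/SS_tot with SS_tot
taken about each pixel's band mean; a spectrally flat pixel (SS_tot = 0) is
assigned CoD 1 when the residual is also zero, else 0, and CoD is clipped
to [0, 1].

The validity filter excludes pixels with CoD below threshold (default 0.9)
or a negative fitted concentration. The fit itself is unconstrained — the
filter, not the solver, handles negativity. Two numerical zeros matter:

- negativity tolerance 10⁻⁹ — a true zero concentration is recovered as
  ± machine noise; values in (−10⁻⁹, 0) are clamped to 0, not excluded;
- THb zero 10⁻⁹ in the SO₂ derivation — a haemoglobin-free pixel's THb is
  round-off dust, and dividing by it would fabricate a saturation value, so
  such pixels become invalid instead.

Excluded pixels carry a 0 sentinel in every concentration-derived map plus
`valid = False`; all statistics consult the mask, never the sentinel. SO₂
is reported in percent (0–100).

The RGB reconstruction weights the bands by a smooth synthetic colour-camera
response (Gaussians at 610/540/465 nm), normalised so unit reflectance maps
to white; the SO₂ overlay blends a colormap of SO₂ over the RGB with
opacity THb/THb_ref (THb_ref = 99th percentile of valid THb), so strong
haemoglobin signal shows oximetry and weak signal shows anatomy.

## Registration and temporal averaging

Motion between sequentially acquired stacks is modelled as pure 2-D
translation — the dominant respiration component at the few-second
timescale of an averaging window — estimated by upsampled frequency-domain
cross-correlation (sub-pixel, ≤ 0.1 px on band-limited content) on a single
alignment band (default: the brightest band of the reference stack) and
applied to all bands of the stack by linear resampling. Intra-stack
(band-to-band) motion is neglected: a single stack acquires in ~0.3 s.
The temporal average is the per-pixel mean; a coverage mask flags border
pixels not covered by every shifted frame. Default window: 6 stacks.
Rotation/deformation are out of scope.

## Profiling

A profile is a line from the proximal to the distal end of the segment,
subdivided into n equal divisions (default 10). ROIs are rectangles centred
at division midpoints, long axis perpendicular to the line, with half-open
membership along the axis ([k·L/n, (k+1)·L/n)) so that default-length ROIs
tile the axis disjointly and boundary pixels bin deterministically. The
transection-decision position (cm) is binned with the same half-open rule;
`mm_per_pixel` comes from configuration (segments are marked at known
intervals), never estimated from imagery.

Statistics per ROI — mean, median, quartiles (linear interpolation), pixel
count — are computed over ROI ∩ tissue-mask ∩ valid. The tissue mask can be
supplied, thresholded (Otsu + largest connected component), or produced by
a gradient watershed from seed markers; the masking stage is deliberately
pluggable.

## Phantom generator

The generator emulates the scene the pipeline targets: a tube-shaped
serosal surface along a horizontal axis with a stepwise longitudinal SO₂
profile (uniform THb, default 1.0 in relative units; within division k,
HbO₂ = THb·SO₂_k/100), optional fat-rich flanking strips with zero
haemoglobin, zero-chromophore background, and a constant scattering offset
(default 0.1). Acquisition simulation adds multiplicative Gaussian noise on
the above-dark signal (σ = 1% of signal by default, approximating shot
noise at high counts) and i.i.d. per-stack translation jitter (default
σ = 2 px) drawn from a seeded generator; applied shifts are returned as
registration ground truth. White/dark levels default to 3500/100 counts on
a 12-bit scale.

Crucially, the forward model does **not** use the unmixing design matrix:
it mixes the wavelength-resolved extinction spectra per unique
concentration tuple on the fine grid and convolves the mixed spectrum with
each passband. Since band convolution is linear, the fit must recover the
concentrations exactly on noise-free input — and does, to ~10⁻¹³ — but the
two code paths are independent, so the round trip is an integration test
rather than a tautology.

What the phantoms do not emulate: spatially varying scattering, specular
highlights, vignetting, wavelength-dependent pathlength, deformable motion,
bile, sensor nonlinearity. Passing round-trip tests therefore demonstrates
the correctness of the computational chain under the model's assumptions,
not the accuracy of those assumptions on real tissue.

## Validation path

The colour-card analysis compares per-panel per-band camera reflectance
means with ground-truth curves convolved through the same `band_convolve`
code path as the chromophore spectra (a single shared implementation, by
construction). Agreement is a Bland-Altman summary: mean paired difference
and ±1.96·SD (sample, n−1) limits of agreement, with a per-wavelength
difference table. The synthetic card (12 panels by default, smooth random
curves bounded to [0.05, 0.95]) gives exact agreement noise-free, a useful
null for the whole validation path.

## Problem sizes and tolerances in the test suite

Round-trip profile tests run at the full 256×512 phantom size (≈ 6200
valid pixels per ROI, ~1 s per phantom) with a 0.05 percentage-point
tolerance; oracle-equivalence tests use 10⁴ random pixels against an
independent normal-equations solver (10⁻⁸) and a 0.1 nm quadrature
reference (10⁻³ relative); stochastic checks use seeded generators with
tolerances derived from the injected noise (delta-method propagation for
temporal stability, allowing for the ~25% sampling error of a
10-acquisition standard-deviation estimate).
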