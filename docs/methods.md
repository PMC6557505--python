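# Methods

This note documents the models, parameter choices and numerical
conventions behind `sevkit`, and what the synthetic-data tests do and do
not demonstrate about real photographs.

## Color model

Conversion follows the standard chain sRGB → linear RGB → XYZ → CIELAB.

- **Transfer function.** Piecewise IEC 61966-2-1 decoding: `v/12.92`
  below 0.04045, `((v+0.055)/1.055)^2.4` above; exact inverse for
  encoding.
- **Primaries and white point.** The published 4-decimal sRGB matrix
  (D65). The CIELAB normalisation white is taken as the XYZ of linear
  RGB (1,1,1) under that matrix — its row sums (0.9505, 1.0000, 1.0890) —
  rather than an independently tabulated D65 white. This guarantees that
  reference white maps to exactly (100, 0, 0) and that every neutral
  gray has a\* = b\* = 0 to machine precision; against implementations
  using higher-precision constants (e.g. scikit-image) the difference is
  below 0.02 CIELAB units, far under skin-measurement noise.
- **Observer.** 2°. Consumer cameras and the sRGB standard assume
  D65/2°; no chromatic adaptation to other illuminants is attempted —
  illumination differences are the calibration stage's job.
- **Gamut handling.** `lab_to_rgb` clips out-of-gamut linear RGB to
  [0, 1] and reports the count of affected pixels on the image
  (`clipped_pixels`) instead of raising: synthetic rendering routinely
  touches the gamut boundary, and silent clipping would hide calibration
  problems while fatal clipping would make rendering unusable. A small
  tolerance (1e-9) keeps pure float round-off out of the count.
- **Integer images** are normalised by their dtype maximum (255, 65535)
  on load. 16-bit output is written as TIFF; 16-bit color PNG is
  refused because no available codec round-trips it.

## Calibration model

The correction is **affine in linear RGB**: observed patch colors `o`
map to reference colors `r` via `r ≈ M·o + c`, fitted by ordinary least
squares over ≥ 4 patches. Affine-in-linear absorbs a global chromatic
cast (M) and an exposure/black-level shift (c), has a closed-form fit,
and is exactly invertible for any affine corruption — a property the
test suite exercises over 100 random casts. Patch means are computed in
linear light so that averaging commutes with the affine model.

Degenerate patch sets (observed colors spanning fewer than 3 dimensions,
e.g. an all-gray card) make the fit underdetermined and raise an error
naming the deficiency. The fit residual reported is the RMS patch error
after correction, in linear-RGB units.

The default 24-patch layout uses the nominal sRGB values of the classic
color rendition chart. Patch *locations* always come from a config file;
automatic card detection is out of scope, matching a workflow where the
operator marks the card once per session.

Limitations: a single affine map cannot correct spatially varying
illumination (vignetting, shadows) or channel crosstalk beyond linear;
patches clipped out of gamut in the photograph break affinity and bias
the fit, which surfaces as a large `fit_residual`.

## Measurement areas and summaries

Masks are binary (nonzero = inside); no feathering or partial-pixel
weighting, since clinical measurement areas are whole regions. Channel
SDs use the population denominator (n) — within one area they describe
pixel scatter, not a sampling estimate. The clinical protocol's floor of
10⁶ pixels per area is enforced as a logged warning, never an error, so
bench-scale synthetic images stay analysable.

## SEV and ΔSEV

Per pixel, `SEV = (l_max − L*) · a*` with `l_max = 100`, the top of the
CIELAB lightness scale; `l_max` is configurable for sensitivity
analysis, and a masked L\* above `l_max` raises (it signals a broken
conversion, not a valid color). The **area SEV is the mean of per-pixel
SEVs**; the SEV of the area's mean color is also exposed
(`sev_of_mean_color`), and the two differ by exactly the covariance of
(−L\*, a\*) over the area — the per-pixel mean is canonical because the
whole point of image-based measurement is that the reaction is
inhomogeneous. ΔSEV subtracts the per-pixel mean SEV of the patient's
contralateral control area; both operands must share `l_max`.

## Statistical layer

Defaults mirror mainstream clinical statistics software:

- **Chi-square**: Pearson, no continuity correction (Yates available via
  `correction=True`); expected counts below 5 append a warning rather
  than failing, since small strata are routine at n = 100.
- **t-tests**: pooled-variance Student by default, Welch behind
  `equal_var=False`; 95% CI from the t distribution. Summary-statistic
  and raw-sample entry points share one code path. A zero-variance
  comparison with unequal means degenerates to p = 0 with a warning.
- **ANOVA + post-hoc**: one-way F-test, then Tukey HSD with the
  Tukey–Kramer unequal-n adjustment (via statsmodels). `posthoc=False`
  skips the pairwise stage for simulation loops.
- **Inter-observer comparison**: chi-square on the observer×grade table
  of marginal grade counts, plus the paired cross-tabulation for
  inspection. The marginal test asks "do the two observers use the grade
  scale the same way?"; it does not measure per-patient agreement
  (a kappa statistic would, and is out of scope).

Simulation checks: under the null, each test's type-I error at α = 0.05
is within ±0.01 of nominal over 2,000 seeded replicates, and t-test
power at an arm-contrast-scale effect (difference 4.2, SDs 4.9/4.0,
n 34/66) matches the noncentral-t closed form within ±3%.

## Synthetic data

**Image generator** (`SkinImageSpec` defaults):

| parameter | default | rationale |
|---|---|---|
| baseline_lab | (66.66, 6.91, 16.53) | control-skin cohort means of a light-skinned (Fitzpatrick 2–4) breast-radiotherapy population |
| erythema_amplitude | 11.8 (peak Δa\*) | flat-field mean ≈ half the peak → mean Δa\* ≈ +5.9, the reported irradiated-minus-control a\* contrast |
| erythema_l_drop | 16.1 (peak ΔL\*) | same construction for the ≈ −8.1 L\* contrast |
| field_smoothness | 12 px | patchy, centimetre-scale reaction at the default 192×288 frame; ≥ 4× the image size short-circuits to a flat field |
| pixel_noise_sd | 0.8 Lab units | sensor/texture noise; within-image SEV variance has no published reference, so this is our calibration |
| image_size | 192×288 | bench scale — orders of magnitude below clinical megapixel areas, chosen so full-pipeline tests run in milliseconds |

The erythema field is min-max-rescaled Gaussian-smoothed seeded noise
times the amplitude, added to a\* and subtracted (scaled) from L\* inside
the irradiated mask only; the card, if rendered, is drawn at reference
colors *before* the cast corrupts the image, so calibration can recover
it. Ground-truth summaries and ΔSEV are bookkept from the exact Lab
field used for rendering.

**Cohort generator** (`CohortSpec` defaults): arms of 66/34 patients;
baseline tones normal with SDs (6.99, 3.16, 4.75); arm effects chosen to
reconstruct the reported per-arm irradiated means (a\* 11.4 vs 15.6,
b\* 13.4 vs 17.0, shared L\* drop) with effect SDs set so total
irradiated a\* SDs land near the reported 4.0/4.9. Fast mode samples
`n_pixels` Lab values per area directly instead of rendering images —
the same estimator the pipeline applies, two orders of magnitude
faster; rendering-based patient images remain available through the
image generator. Observer grades are a threshold function of true ΔSEV
(cutoffs 250/480) with observer-specific threshold offsets (0, +130 —
the second observer grades more leniently, reproducing the direction and
rough magnitude of reported grade-marginal disagreement) plus an 8%
chance of a ±1 slip.

**What passing tests show — and don't.** The generator demonstrates
internal consistency: the pipeline recovers known colors through
rendering, calibration undoes known casts, ΔSEV's across-patient scatter
shrinks when baseline tone varies (the subtraction's purpose), and the
statistical layer is calibrated. It does **not** model specular
highlights, skin texture and hair, vignetting or non-uniform
illumination, camera RAW processing, or pose differences between the two
measurement areas — so passing tests cannot certify accuracy on real
photographs acquired outside the protocol's "uniform lighting, no shiny
reflections" conditions.

## Numerical conventions

- All images are float64 in [0, 1] in memory; quantization only on I/O.
- Every stochastic component takes a mandatory integer seed
  (`numpy.random.default_rng`); identical seeds give bit-identical
  output.
- Validation errors are raised eagerly at dataclass construction;
  warnings (area minimum, small expected counts, zero variance) are
  logged or attached to results, never silently dropped.
- The ΔSEV self-consistency identity (`value = measured − baseline`) and
  the covariance identity between the two SEV aggregations are enforced
  by construction and verified against loop-based oracles in the tests.

## Known limitations

- No ICC profile handling: inputs are assumed sRGB-encoded.
- The calibration model is global affine; scene-dependent illumination
  fields are out of scope.
- Grade simulation is a minimal threshold model — adequate for testing
  the statistical layer, not a behavioral model of clinical grading.
- Reported cohort-level results from any specific patient population are
  not reproducible here by construction; the package reproduces the
  *method* and the statistics computable from published summary tables.
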