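# Methods

## The model

A filter is represented purely by its spectral transmittance F(λ) ∈ [0, 1]
on a working grid (default 380–780 nm at 1 nm — the integration bounds of
the metric formulas). Everything the package computes follows from weighting
F against fixed reference functions under the D65 daylight illuminant:

* weighted transmittances are rectangle-rule (Riemann) sums
  Σ F·E·S Δλ / Σ E·S Δλ, with Δλ the grid step. The rectangle rule matches
  the defining summation formulas exactly; a 0.1 nm brute-force oracle in the
  test suite confirms the 1 nm value agrees to better than 10⁻³.
* chromaticities are CIE 1964 10° tristimulus integrals projected to
  CIE 1976 u′v′ (u′ = 4X/(X+15Y+3Z), v′ = 9Y/(X+15Y+3Z)); the colour shift is
  the Euclidean Δu′v′ of the D65 white point, reported dimensionless.
* the gamut ratio is area(hull of 99 reflectance chromaticities under
  filtered D65) / area(hull unfiltered), hull areas via Qhull (equal, for 2-D
  input, to the shoelace value on the hull vertices — verified against an
  all-triangles brute-force oracle).

Assumptions worth stating: the retina is treated trichromatically through
the large-field observer; scattering, polarisation, UV transmission and
chromatic adaptation are outside the model; melanopsin attenuation is an
instantaneous spectral weighting, not a prediction of downstream circadian
outcomes.

## Reference functions

**Observer and illuminant.** The CIE 1964 10° colour-matching functions and
the D65 spectral power distribution are bundled as their standard 10 nm
tabulations and PCHIP-resampled to the working grid. Cross-check: the D65
chromaticity computed from the bundled tables reproduces the published
CIE 1964-observer value (x₁₀, y₁₀) = (0.31382, 0.33100) to ≈3×10⁻⁵, which
the test suite asserts at 10⁻⁴.

**Melanopic sensitivity.** Constructed, not tabulated: the Govardovskii
A1-pigment alpha-band template at λ_max = 480 nm (quantal), multiplied by λ
(quantal→energy conversion up to a constant) and by an ocular-media
transmittance, then renormalized to peak 1. The construction mirrors how the
standardized melanopic action spectrum is defined; with the default lens the
peak lands at 490 nm. The beta (cis) band of the pigment template is not
included.

**Ocular media.** The lens model is a deliberately simple analytic form
written for this package: optical density D(λ) = 0.48·e^(−(λ−400)/60) above
400 nm (T ≈ 0.33 at 400 nm, 0.62 at 450 nm, ≈1 beyond 600 nm), approximating
adult ocular media. It is not an age-resolved standard tabulation;
`lens_model_id="none"` disables pre-receptoral filtering entirely, and the
identity-lens construction then reduces exactly to the pigment template.

**Reflectance set.** The canonical 99 colour-evaluation samples are not
redistributable, so the default set is a seeded synthetic stand-in: 99
smooth reflectances (neutral base + 1–3 signed Gaussian bumps, clipped to
[0.02, 0.95], fixed seed 20990). `source_id` records this in every output.
Consequence: absolute gamut-ratio values differ slightly from what the
measured sample set would give; ratios, orderings and correlations — the
quantities the framework interprets — are robust to the substitution, but
published gamut numbers for specific commercial filters should not be
expected to match to the digit.

## Cleaning pipeline

Digitized curves are interpolated with PCHIP (shape preserving, exact at the
knots, no overshoot beyond local data), evaluated on the grid, then: values
strictly outside the measured span are set to exactly 0 (unmeasured edges
contribute nothing to the integrals); negative values are set to exactly 0;
bounded kinds above 1 are clipped to 1 with a warning (the symmetric
artefact; the negative rule's counterpart). Duplicate wavelengths are
averaged at read time. The pipeline is idempotent, and interpolation happens
before zero-fill, so the fill applies strictly outside [min, max] of the raw
wavelengths.

## Analytic filter models

Sigmoid cut-off T(λ) = L/(1+e^(−k(λ−λ₀))) with λ₀ (nm), L ∈ (0,1],
k > 0 nm⁻¹; default sweep ranges λ₀ ∈ [450, 600] step 10 nm, L ∈ [0.1, 0.9]
step 0.1, k ∈ [0.05, 1.0] log-spaced (ten points). Neutral density:
constant T (density d ⇔ T = 10⁻ᵈ). Notch: unit transmittance outside a stop
band of configurable centre/width/depth with 10 nm raised-cosine edges — the
edge shape is this package's choice, since no analytic notch form is
standard. Structural facts the sweeps exhibit (and the tests pin down):
plateau sweeps rescale both transmittances proportionally with exactly
constant chromaticity — a line of slope 1 in log-attenuation space parallel
to the neutral-density locus; cut-off sweeps drive the melanopic/luminous
ratio monotonically down; every monotone long-pass filter satisfies
melanopic ≤ luminous transmittance.

## Synthetic filter survey

`generate_synthetic_database` emulates a survey of commercial filters
digitized from published graphs: 121 filters split 76 medical / 11 safety /
34 task-specific (10 sport, 4 driving, 12 VDU, 8 other) by largest-remainder
rounding; shape mixture 70 % sigmoid cut-offs, 15 % Gaussian notches, 15 %
flat plateaus; medical filters drawn at longer cut-offs (470–600 nm) than
the rest (420–540 nm), reflecting deep blue-blockers in medical use; raw
curves sampled on jittered 2–5 nm grids, with a 40 % chance each of a
truncated short- or long-wavelength edge, plus additive digitization noise
(sd 0.01) that produces occasional negative dips. Every record keeps both
the raw and cleaned spectrum, so the generator exercises the entire cleaning
path. What the generator does **not** emulate: manufacturer-specific curve
families, correlated noise from graph-axis miscalibration, or real category
base rates of filter shapes — so database-level statistics (e.g. the metric
correlation matrix, which for the default seed gives r(luminous, melanopic)
≈ 0.83, r(melanopic, colour shift) ≈ −0.84, r(colour shift, gamut) ≈ −0.81)
reproduce the *structure* seen in real filter surveys (strong positive
transmittance coupling, strong negative colour-shift couplings), not any
particular survey's decimals.

## Pupil model

Unified light-adapted formula: Stanley–Davies term
D_SD = 7.75 − 5.75·(F/846)^0.41/((F/846)^0.41+2) on corneal flux density
F = L·a·M(e) (field area a in deg², M = 0.1 monocular / 1 binocular), plus
the age term (y − 28.58)·(0.02132 − 0.009562·D_SD). Defaults: 150° field,
32 years, binocular. Valid ages 20–80; diameters outside 2–9 mm are clamped
with a warning rather than silently. Retinal illuminance (trolands) is
effective luminance L·T × pupil area; the default luminance grid is
10⁻³–10⁴ cd/m², 50 log-spaced points. Spectrally selective (melanopsin
driven) pupil effects are not modelled — the model is applied to spectrally
uniform filters only.

## Numerical choices and degenerate inputs

* Transmittance integrals require a strictly positive weighting integral;
  a zero denominator raises rather than returning NaN.
* Fully opaque filters: no transmitted white point exists, so the colour
  shift is reported as 0 with the gamut flagged degenerate (ratio 0).
* Near-black filtered reflectances are excluded from the hull with a count,
  instead of failing the whole gamut computation; fewer than three surviving
  chromaticities → ratio 0 with a degenerate flag.
* The gamut ratio is not clamped at 1; exotic filters could in principle
  enlarge the hull, and that would be reported as > 1.
* Flat-filter exactness (colour shift 0, gamut ratio 1) holds to double
  precision round-off (~10⁻¹⁶), asserted at 10⁻¹².
* All randomness flows through explicit integer seeds; two runs of the
  fixture + analysis pipeline with one seed are byte-identical.

## Problem sizes

Defaults used throughout the examples, tests and the acceptance script:
401-point grid, 99 reflectances, 121-filter survey, 500-filter identity-line
sweep, 50-point luminance grid. A full survey analysis (cleaning, four
metrics per filter including two 99-hull computations) takes a few seconds.

## Known limitations

The observer, illuminant and pigment template are faithful standard forms,
but the lens model and reflectance set are documented synthetic stand-ins;
absolute melanopic and gamut values therefore carry a model component.
Colour shifts are straight-line distances in u′v′ — adequate near the white
point, progressively less perceptually uniform toward the spectral locus.
No attempt is made to fit sigmoid parameters to measured spectra, to handle
polarisation/scatter, or to model adaptation to chronically worn filters.
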