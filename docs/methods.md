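# Methods

This note documents the models, defaults and numerical choices behind
`fpcalib`, and what the synthetic-data generator does and does not emulate.

## Data model and units

All plate-reader data is exchanged as a tidy long table (one row per
well/time/measure/wavelength/gain reading) with layout metadata joined at the
reading boundary; wide instrument exports are unpivoted through an explicit
per-dialect configuration rather than auto-detection, so parsing is
deterministic. Units are fixed package-wide: minutes, nm, µl, cm, ng/µl and
molar. Every stochastic routine takes a single integer seed.

## Absorbance processing

**Path length.** Microwell optical paths vary with fill volume and meniscus.
The default estimator uses the near-infrared water absorbance band: the
differential `A(975) − A(900)` (each a mean over ±2 nm) divided by the
instrument constant `k_water_per_cm` (default 0.172 per cm, re-measurable with
buffer-only wells). A volume → path geometry table is available as a fallback
for spectra without water-band coverage. Because light scatter also declines
slowly across 900–975 nm, scatter-contaminated wells bias the water
differential slightly low (≈0.5% at the default scatter amplitude); this is
visible in the tests and accepted as within assay tolerance.

**Scatter.** Particulate scatter is modelled as `A = a·λ^b` fitted over
700–900 nm — above FP chromophore bands, below the water band — with the
exponent clipped to [−4.5, 0]. The fit is seeded in log–log space and then
refined by least squares in linear space: with additive photometric noise the
log–log fit censors small and negative readings and extrapolates with a
systematic positive bias, which the linear-space refinement removes. The
fitted baseline is subtracted under the analysis bands.

**Band reads.** `absorbance_at` takes a simple mean over λ ± halfwidth
(default 2 nm); filter-transmission weighting is not attempted because
transmission curves are generally unpublished. Negative post-blank absorbances
are retained so noise statistics stay unbiased; only final concentrations are
floored at zero.

## Concentration assays

`C (M) = A_corrected / (EC · L)` for the A280 (EC280, pure protein only) and
ECmax (chromophore-specific, lysate-valid) assays; ng/µl follows as
`C · MW · 10³` (1 M × MW g/mol = MW g/L ≡ MW·10³ ng/µl). The microBCA assay
inverts a monotone polynomial BSA standard curve (default cubic, anchored
through the zero standard) by bisection to 10⁻⁶ ng/µl, after subtracting a
pre-reagent baseline read that removes the intrinsic A562 absorbance of red
FPs.

**Detection vs quantification.** Besides the per-assay sensitivity defaults
(ECmax 0.1, A280 1, microBCA 2 ng/µl), each Beer's-law estimate carries a
per-well noise floor: 3× the scatter-fit residual RMS, amplified by the
power-law lever arm `(λ_window/λ_band)^|b|` that magnifies in-window noise
when the baseline is extrapolated to the analysis band. Wells below this floor
are flagged below-LOD; quantitative accuracy (the ~5% regime) is only expected
above roughly (10/3)× the floor, the usual 10σ limit of quantification.

**Dilution-series fitting.** Duplicates are averaged per dilution factor,
points under the assay LOD are discarded, and concentration is regressed on
1/dilution (ordinary least squares, ≥3 points); the stock concentration is the
prediction at dilution factor 1. The conc ~ 1/dilution form was chosen over a
log–log fit for unit interpretability of slope and intercept.

## Conversion factors

`generate_cfs` blank-subtracts each gain's fluorescence series, removes
saturated readings, and fits net RFU against molecules per well through the
origin (`cf = Σxy/Σx²`). The zero intercept is deliberate: the blank is already
subtracted, and a free intercept would silently re-absorb blank drift.
Saturation is detected two ways: a hard detector ceiling from configuration
(compared against the raw reading, i.e. shifted by the blank), plus a top-down
log–log local-slope test that trims points where the slope to the next point
departs from 1 by more than 0.2 — a saturating detector bends the log–log
response flat even below any nominal ceiling. Gain curves are cubic
polynomials in log₁₀(cf) vs gain, fitted over ≥5 gains and refusing to
extrapolate.

## OD calibration

Microsphere stock particle counts derive from mass concentration via the
per-sphere mass `ρ·(π/6)·d³` assuming perfect monodispersity at the nominal
d50 (0.890 µm, 2.0 g/cc → 1.355 × 10¹² spheres/g; the vendor CV of 3.2%
justifies the point-mass approximation). Blanked OD/cm is fitted against
particles per well through the origin; particles-per-OD is the reciprocal
slope. R² < 0.95 flags multiple-scattering nonlinearity without aborting.

## Brightness normalization

Relative brightness is `EC · ex.eff · QY · em.eff` with band sums over the
normalized spectra in 1 nm steps: `ex.eff` sums normalized excitation over the
excitation band; `em.eff` is the emission band sum divided by the total
emission sum. Band endpoints are inclusive integers; half-integer filter edges
round inward, making the sums reproducible bit-for-bit. `CFnorm = CF ·
brightness_ref / brightness_cal`; normalizing to a reference and back is the
identity to rounding error.

## Timecourse processing

`process_plate` applies, in order: media-blank OD subtraction (nearest
timepoint; negatives floored and flagged) and per-cm normalization; PEMS cell
counts; autofluorescence subtraction; de-quenching; conversion to MEFP; per-cell
division; molar conversion. Autofluorescence is subtracted **before**
de-quenching because the background is emitted from inside the same quenching
suspension — both signals are attenuated together, so the FP-specific signal
must be isolated first (the ordering is this package's choice; it is exactly
invertible on simulated data).

**Autofluorescence** is a monotone piecewise-linear map from OD/cm to
control-strain RFU, averaged per OD, repaired by pool-adjacent-violators if
non-monotone, and clamped to the calibrated OD range.

**Quenching** defaults to `retained(OD) = exp(−k·OD)`, fitted by nonlinear
least squares (k ≥ 0) to the per-row retained fractions of a mixing assay
(purified FP ± non-fluorescent cells). A single parameter reproduces the
observed regime — under 20% loss below OD600/cm 0.5, ≈30% around OD 2 — while
guaranteeing `retained(0) = 1` and monotonicity. Correction divides net RFU by
the retained fraction and refuses to extrapolate below a retained fraction of
0.2. Per-cell values are suppressed below 10⁵ particles because division by
near-zero early-timepoint cell counts explodes.

**Molar concentration** uses the OD-specific total cell volume of 3.6 µl per
OD600/cm per ml of culture, making concentrations growth-rate independent.
When only OD700 is measured, it can be mapped through the reference OD600~OD700
line from `od_ratio_analysis`, which fits uninduced wells (optionally after
media blanking, which otherwise shifts the intercept by `blank·(1−m)`) and
reports each observation's OD600 as a ratio to its prediction.

## Synthetic data

The generator emulates: Beer's-law chromophore absorption as a single Gaussian
(σ 15 nm) at the peak excitation wavelength scaled by ECmax, an aromatic
280 nm Gaussian (σ 10 nm) from EC280 with an optional non-FP background
multiplier for lysates, λ⁻⁴ scatter, a water band realized as a smooth ramp
(905–945 nm) whose plateau encodes `k_water · path`, additive absorbance noise
(σ 0.002), multiplicative fluorescence noise (CV 2%), a detector ceiling,
exponential quenching, linear-in-OD autofluorescence, logistic growth and a
linear OD600–OD700 relation (slope 1.30, intercept −0.02 for uninduced
cultures). Defaults: 500 ng/µl stock, 11 two-fold dilutions at 225 µl
(0.58 cm path), gains 40–120 with `cf = 2×10⁻¹³·10^(0.025·gain)` RFU/molecule,
1.6 × 10⁸ particles per OD600/cm per 200 µl well and a constant 10,000
molecules/cell expression trajectory — magnitudes consistent with overexpression
assays in high-copy vectors.

It does **not** emulate spectral fine structure of chromophores, real
water/medium spectra, cell-shape-dependent scatter, pH- or
maturation-dependent brightness, or plate-position effects. Passing tests
therefore demonstrate the correctness and invertibility of the analysis on a
faithful instrument model, not robustness to those real-world effects.

Fixture photophysics for mTagBFP2, mGFPmut3, mCherry and fluorescein use
representative literature constants; their packaged spectra are synthetic
Gaussian stand-ins (the fixture file is named accordingly), adequate for
band-sum arithmetic, not spectroscopy.

## Problem sizes

The test suite and the acceptance script run simulations at desk scale:
dilution series of 11 points, growth plates of 3 + 3 + 1 wells × 40
timepoints, and 20–100 seeded repetitions for the stochastic summaries. These
sizes give stable medians for every reported quantity while keeping a full run
in seconds.

## Known limitations

* The water-band path estimator needs 900–980 nm coverage and a per-instrument
  constant; scatter-heavy wells bias it slightly low.
* The exponential quench form is a one-parameter convenience; strongly
  non-exponential attenuation would need the monotone alternative.
* The FPbase API client parses the common record shape only and falls back to
  Gaussian spectra when the spectra endpoint is unavailable; it is exercised
  offline through its cache path.
* OD600↔OD700 cross-wavelength microsphere corrections are out of scope; users
  choose which OD channel anchors PEMS and the choice is recorded in the run
  manifest.
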