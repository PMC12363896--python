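# Methods

This note documents the models, algorithms and numerical choices behind
`eemshift`, and what the synthetic validation does and does not
demonstrate about real measurements.

## Data model and preprocessing

An EEM is a matrix of detector counts indexed `[excitation, emission]` —
a stack of emission spectra acquired at stepped excitations. Default
axes mirror common NIR practice: excitation 650–900 nm in 1 nm steps,
emission 600–1000 nm at 0.5 nm resolution. Intensities are arbitrary
counts; no radiometric calibration is attempted.

Two corrections precede every analysis:

* **Control subtraction.** The matched blank (0 μM fluorophore) EEM is
  subtracted elementwise. Negative differences are *retained*: clipping
  them to zero would add a positive bias to every integrated area in
  low-signal regions. Grids must agree to within 10⁻⁶ nm — mismatched
  grids are an error rather than an implicit resampling, because blanks
  are acquired on the same instrument grid as their samples.
* **Integration-time rescaling.** Counts scale linearly with integration
  time, so a spectrum recorded at half the reference time has its counts
  doubled before comparison. Composition of rescalings equals a single
  rescale to the final reference (tested).

## Robust smoothing (RLOESS)

Scattering media superimpose a narrow first-order scattering ridge along
`λ_em ≈ λ_ex`. The smoother is a from-scratch robust locally weighted
quadratic regression, applied independently to each emission spectrum:

* **Window**: all points within `span/2` of the target wavelength
  (span in nm, default 40, so ~81 points on a 0.5 nm grid). Defining the
  window in wavelength rather than point count keeps uneven grids
  sensible. Windows become asymmetric at the spectrum edges; no padding
  or reflection invents data outside the measured range.
* **Distance weights**: tricube `(1 − (d/d_max)³)³` with `d_max` the
  farthest in-window distance.
* **Robust weights**: bisquare `(1 − u²)²` for `|u| < 1` with
  `u = r / (6 × median|r|)`, recomputed from the residuals of the
  previous full pass, iterated 5 times by default. Exactly-zero
  residuals short-circuit the iteration; if the median absolute residual
  is exactly zero while some residuals are not, the deviating points get
  zero weight.
* **Degenerate-scale floor.** On strictly noise-free spectra the global
  median absolute residual collapses to the local-fit *bias* scale
  (curvature the quadratic cannot represent), and the bisquare would
  treat the entire curved band as outlying, with chaotic peak wander of
  several nm. The robust scale is therefore floored at a small fraction
  (default 10⁻³) of the spectrum's amplitude range. On realistically
  noisy data the median residual dominates and the floor is inactive.
* **Fallback.** A window whose total weight is degenerate (fewer than
  three points with nonzero weight) falls back to the unweighted local
  quadratic fit.

Properties verified by the test suite: exactness on global polynomials
of degree ≤ 2 regardless of robust iterations; shift and positive-scale
equivariance; agreement with an independent brute-force implementation
(explicit normal equations, explicit weight recomputation) to ≤ 10⁻⁶
relative error on random spectra; suppression of a diagonal ridge at
twice the band height so the per-row argmax stays within 1 nm of the
band centre; and peak stability within one grid step under 5%
contamination with 10× spikes.

Smoothing an EEM is strictly row-wise, so smoothing only the rows a
given analysis extracts is mathematically identical to smoothing the
whole matrix; pipeline code exploits this to keep full-resolution
(251 × 801) analyses fast.

## Spectral metrics

* **Peak**: argmax of the processed spectrum; wavelength ties break
  toward the lower wavelength everywhere, making all results
  deterministic.
* **AUC**: trapezoidal integral over a wavelength range (default
  650–1000 nm); bounds falling inside the grid are handled by linear
  interpolation of the end intervals. AUC is additive over adjacent
  ranges to 10⁻⁹ relative.
* **Centroid**: the equal-area wavelength — where the cumulative
  trapezoidal area first reaches half the total, located by linear
  interpolation inside the bracketing interval. Computed on the
  control-subtracted spectrum with negatives retained; if negatives make
  the cumulative area non-monotone, the *first* half-area crossing is
  used. Sub-grid interpolation is reported, then rounded to 0.5 nm in
  presentation tables.
* **Stokes shift**: emission maximum − excitation maximum; a negative
  value is flagged with a warning but returned.
* **Uncertainty**: wavelength accuracies combine in quadrature,
  `u = √(u_ex² + u_em²)`; with ±1 nm on each axis the Stokes-shift
  uncertainty is ±1.4 nm.
* **Scan tables** report per-excitation peak, intensity, centroid and
  AUC, with intensity and AUC also as ratios of the scan maximum
  (brightest row prints 1.00); presentation rounding is 0.5 nm for
  wavelengths and 2 decimals for ratios, while internal values keep full
  precision.

## Excitation-dependence model

`ExcitationShiftModel` holds a peak- or centroid-vs-excitation curve;
`fit()` estimates the red-shift slope and classifies the behaviour:

* **Slope**: `least_squares` (default) is the OLS slope over the fit
  range, with its standard error from the OLS fit; `endpoint` divides
  the response difference between the first and last in-range points by
  their separation. Both are reported because the endpoint estimator
  reproduces printed table arithmetic exactly while OLS uses all points.
* **Classification**: `excitation_independent` when the total response
  range is ≤ `flat_tol` (default 1 nm) *and* |OLS slope| ≤ `slope_tol`
  (default 0.05 nm/nm); otherwise `rees` when the response never drops
  more than `flat_tol` below its running maximum (monotone rise with
  hysteresis); otherwise `anti_kasha_non_monotonic`. The defaults were
  chosen so a ~0.5 nm-range solvent curve classifies independent while
  curves spanning 14–15 nm classify dependent; both thresholds are
  parameters and are echoed in reports.
* **Bump detection** runs below the slope fit range by default (so a
  pre-onset local maximum is not double-counted as part of the REES
  rise) and returns the tallest interior local maximum with positive
  prominence. Note that prominence is measured to the higher surrounding
  minimum, so a bump whose own tail raises its base reports a prominence
  somewhat below its programmed height.

Sampling matters for classification: a ~2 nm bump of ~8 nm width at
745 nm is resolved at 5 nm curve steps, but 10 nm sampling can quantize
it to exactly the hysteresis tolerance.

## Concentration series and inner filtering

* **Linear range**: the longest contiguous run of consecutive
  concentration pairs whose log–log intensity slope lies within a
  tolerance (default 0.1) of 1. This pairwise criterion is
  scale-invariant and order-independent, unlike residual thresholds on a
  global fit.
* **CDRS**: per-concentration emission peak wavelength and maximum
  intensity at a fixed excitation, normalized to the series maximum.
* **Beer–Lambert**: `ε = OD / (c·10⁻⁶ · l)` with concentration in μM and
  pathlength in cm; transmission is `10^(−OD)`. Transmission
  comparisons between media are read in percentage points of
  transmitted fraction.
* **Divergence**: FWHM and peak-position differences between
  max-normalized absorbance and excitation spectra; half-maximum
  crossings are linearly interpolated, and an unbracketed half-maximum
  is an error rather than a guess.

## Synthetic generator

The generator is a forward model of the study conditions, not a fixture:

* **Band shape**: exponentially modified Gaussian (Gaussian core of
  width σ convolved with an exponential tail of decay `|skew|·σ`),
  re-anchored so its *mode* sits at the programmed wavelength. The EMG
  was chosen over a skew-at-the-peak shape because real NIR dye bands
  pair a locally near-symmetric peak with a long red tail: only that
  combination reproduces both the observed ~10–12.5 nm centroid−peak
  gaps and the stability of measured peaks under robust smoothing.
* **Excitation dependence**: band mode
  `μ(λ_ex) = μ₀ + s·max(0, λ_ex − onset) + bump(λ_ex)` and width
  `σ(λ_ex) = σ₀ + broadening·max(0, λ_ex − onset)`. With `s = 0`, no
  bump and no broadening the EEM is exactly rank one (separable) —
  Kasha-rule behaviour.
* **Presets** bundle parameters for three microenvironments: `dmso`
  (excitation-independent, envelope peak 792 nm, emission mode
  826.5 nm), `bsa` (envelope 794 nm, mode 813.5 nm at the envelope peak,
  REES slope 0.35 nm/nm above 760 nm, bump at 745 nm), and `resin`
  (envelope 809 nm, mode 823.5 nm, slope 0.39 nm/nm, broadening
  0.05 nm/nm, bump at 745 nm). Band widths and tail strengths were
  calibrated once against the published per-excitation tables
  (centroid−peak gaps of 10 / 11.5 / 12.5 nm); amplitudes
  (10000 / 4700 / 5400 counts) encode the relative brightness of the
  three media so cross-medium AUC comparisons are qualitatively
  realistic. True lineshapes of the measured samples are unpublished;
  presets match printed peak, centroid and Stokes values only.
* **Artifacts**: a Gaussian scattering ridge centred at `λ_em = λ_ex`
  (σ 3 nm); multiplicative banding stripes (ripple of ~10 nm period
  along emission) confined to excitation 820–860 nm — banding is a
  row-wise gain change, so row-wise smoothing attenuates the within-row
  ripple but the row-to-row intensity depression survives, as it does in
  real data; heteroscedastic noise with standard deviation
  `√((noise_scale·I)² + read_noise²)`. Sample and control share the
  deterministic ridge and banding but draw noise from independent
  substreams of one integer seed, so control subtraction cancels the
  structure exactly in the noise-free limit and output is
  bit-reproducible per seed.
* **Inner filtering**: right-angle cuvette with a centred observation
  volume (`d_ex = d_em = l/2`); per concentration,
  `EEM_c = c · ideal · 10^(−A(λ_ex)·d_ex/l) · 10^(−A(λ_em)·d_em/l)` with
  `A = ε·c·l`. The default extinction curve is a blue-tailed EMG peaking
  at 792 nm scaled to ε = 167,000 L·mol⁻¹·cm⁻¹, so 1 μM over 1 cm gives
  OD 0.167. Because ε overlaps the blue edge of the emission band,
  increasing concentration red-shifts the apparent emission peak
  (CDRS) and rolls intensity off at the top of the series.

**What the synthetic data do not emulate**: aggregation equilibria,
photobleaching, lifetime effects, polarization, lamp-spectrum structure
beyond the banding stripes, and wavelength-dependent detector response.
Passing tests therefore demonstrate that the *pipeline* recovers
programmed spectral laws under realistic ridge/banding/noise artifacts —
not that those laws hold for any particular real sample.

## Problem sizes and runtime choices

Validation runs use full-resolution grids (251 excitations × 801
emission pixels) where the claim depends on grid resolution (slope
recovery, preset maxima) and reduced grids elsewhere. The
slope-recovery check generates 10 seeded EEM pairs and averages the
recovered endpoint slope; the per-slope parameter-recovery property uses
5 seeds for each of four programmed slopes. Peak positions quantize to
the emission grid (0.5 nm), which bounds per-seed slope scatter at
roughly ±0.0125 nm/nm per table step; seed averaging removes most of
it.

## Known limitations

* Robust smoothing of a band whose width is comparable to the span
  leaves a small peak-flattening bias; with the default span this is
  below one 0.5 nm grid step for the preset lineshapes, but it grows
  with span⁴ and with band asymmetry.
* The centroid of a spectrum with large negative excursions (heavy
  subtraction noise) relies on the first half-area crossing; it is
  deterministic but can be sensitive near zero total area.
* Classification thresholds are heuristics over curve geometry, not
  hypothesis tests; the OLS standard error in the results object is the
  statistically interpretable quantity.
* The vendor's raw export format is not parsed; only the two documented
  CSV dialects are supported.
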