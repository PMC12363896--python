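# eemshift

Excitation–emission matrix (EEM) processing and red-edge excitation shift
analysis for near-infrared fluorophores.

Indocyanine green (ICG), the workhorse fluorophore of fluorescence-guided
surgery, does not always obey the Kasha–Vavilov rule: bound to serum albumin
or embedded in a printed resin matrix, its emission spectrum depends on the
excitation wavelength, red-shifting by ~0.3–0.4 nm per nm of excitation at
the red edge of the absorption band (a red-edge excitation shift, REES) and
showing a non-monotonic local maximum below the REES onset. `eemshift` is a
toolkit for quantifying that behaviour from EEMs: robust preprocessing,
excitation-specific spectral metrics, shift-curve modelling, and
concentration-series / inner-filter diagnostics, together with a synthetic
EEM generator that reproduces the artifact structure of real
spectrofluorometer data so that every stage of the pipeline is testable
without instrument access.

## What it computes

Given a sample EEM `I(λ_ex, λ_em)` and a matched blank (0 μM) control:

1. **Preprocessing** — control subtraction (negative counts retained) and
   integration-time rescaling (`eemshift.core`).
2. **Robust smoothing** — from-scratch RLOESS: locally weighted quadratic
   regression per emission spectrum, tricube distance weights × iterated
   bisquare robust weights with cutoff `6 × median|r|`, span 40 nm. Narrow
   scattering ridges along `λ_em ≈ λ_ex` are rejected as outliers; nothing
   is smoothed across the excitation axis (`eemshift.smoothing`).
3. **Spectral metrics** — per-excitation emission peak, equal-area centroid
   (wavelength where the cumulative trapezoidal area reaches half the
   total), trapezoidal AUC over 650–1000 nm, Stokes shift
   `λ_em^max − λ_ex^max`, and the quadrature uncertainty
   `u = √(u_ex² + u_em²)` (`eemshift.metrics`).
4. **Shift analysis** — peak- or centroid-vs-excitation curves, red-shift
   slopes `s` (endpoint or ordinary least squares, nm/nm), classification
   into excitation-independent / REES / anti-Kasha-non-monotonic behaviour,
   and pre-onset bump detection, wrapped in a statsmodels-style
   `ExcitationShiftModel → fit() → ExcitationShiftResults` pair
   (`eemshift.shift`).
5. **Concentration analysis** — proportional (linear) range from pairwise
   log–log slopes, concentration-dependent red shift (CDRS) curves,
   Beer–Lambert molar extinction `ε = A/(c·l)`, transmission `10^(−OD)`,
   and absorbance-vs-excitation divergence driven by inner filter effects
   (`eemshift.concentration`).
6. **Synthesis** — parametric EEM generator: mode-anchored
   exponentially-modified-Gaussian bands with programmable REES slope,
   onset, anti-Kasha bump and broadening; scattering ridge, banding
   stripes, seeded heteroscedastic noise, and primary/secondary
   inner-filter attenuation `10^(−A(λ_ex)d_ex/l) · 10^(−A(λ_em)d_em/l)`
   (`eemshift.synthetic`).

## Worked example

Generate a synthetic albumin-like EEM (programmed peak red-shift
0.35 nm/nm above a 760 nm onset, scattering ridge and noise), process it
through the full pipeline, and fit the shift model:

```python
import dataclasses
from eemshift import (ExcitationShiftModel, SmoothingConfig, add_artifacts,
                      ideal_eem, medium_preset)
from eemshift.synthetic import default_em_grid, default_ex_grid

fluor, artifacts = medium_preset("bsa")
eem = ideal_eem(fluor, default_ex_grid(), default_em_grid())
sample, control = add_artifacts(eem, dataclasses.replace(artifacts, seed=11))

model = ExcitationShiftModel.from_eem(
    sample, "peak", ex_lo=770, ex_hi=810, step=10,
    control=control, smoothing=SmoothingConfig(span=40))
print(model.fit(fit_range=(770, 810)).summary())
```

```
Excitation-dependence analysis
==============================================
response:          peak wavelength (nm)
curve points:      5 (770-810 nm)
fit range:         770-810 nm
slope method:      least_squares
red-shift slope:   0.3400 nm/nm (OLS se 0.0141)
classification:    rees  [flat_tol=1 nm, slope_tol=0.05 nm/nm]
local bump:        none detected
==============================================
```

The fitted slope (0.34 ± 0.01 nm/nm) recovers the programmed 0.35 nm/nm
red-edge shift to within the grid resolution, and the monotone rise over
770–810 nm is classified as REES. Fitting over 700–810 nm instead exposes
the programmed local maximum near 745 nm and the classification switches to
`anti_kasha_non_monotonic`.

The same pipeline is available from the shell:

```bash
eemshift simulate --preset bsa --seed 11 --out s.csv --control-out c.csv
eemshift scan --in s.csv --control c.csv --ex 770:810:10 --out table.csv
eemshift rees --in s.csv --control c.csv --ex-range 770:810:10 --report rees.json
```

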