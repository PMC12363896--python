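"""Spectral summary metrics extracted from EEMs.

Per-excitation emission spectra are characterised by four numbers that
together describe both where the photons are and how they are distributed:

* **peak** — wavelength and height of the intensity maximum;
* **AUC** — integrated emission over a wavelength range, by the trapezoid
  rule (default range 650-1000 nm);
* **centroid** — the equal-area wavelength, where the cumulative
  integrated emission first reaches half of the total;
* **Stokes shift** — emission maximum minus excitation maximum.

Wavelength tie-breaks always favour the lower wavelength, so every metric
is deterministic.  Reported wavelength uncertainties combine excitation
and emission calibration uncertainties in quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import EEM, Spectrum, WavelengthGrid
from .exceptions import RangeError

__all__ = [
    "PeakSummary",
    "UncertaintyBudget",
    "ExcitationScan",
    "emission_spectrum_at",
    "excitation_spectrum_at",
    "peak",
    "auc",
    "centroid",
    "eem_maxima",
    "stokes_shift",
    "quadrature_uncertainty",
    "normalize",
    "excitation_scan",
]

#: default integration bounds in nm for AUC and centroid
DEFAULT_AUC_RANGE = (650.0, 1000.0)


@dataclass(frozen=True)
class PeakSummary:
    """One row of an excitation scan table."""

    excitation: float  # nm (actual grid wavelength used)
    peak_wavelength: float  # nm
    peak_intensity: float  # counts
    centroid: float  # nm
    auc: float  # counts * nm


@dataclass(frozen=True)
class UncertaintyBudget:
    """Wavelength calibration uncertainties, combined in quadrature."""

    u_excitation: float = 1.0  # nm
    u_emission: float = 1.0  # nm

    @property
    def u_stokes(self) -> float:
        return quadrature_uncertainty(self.u_excitation, self.u_emission)


def _nearest_index(grid: WavelengthGrid, target: float, axis_name: str) -> int:
    v = grid.values
    if target < v[0] or target > v[-1]:
        raise RangeError(
            f"{axis_name} {target} nm outside grid range [{v[0]}, {v[-1]}] nm"
        )
    j = int(np.searchsorted(v, target))
    if j == 0:
        idx = 0
    else:
        d_lo, d_hi = target - v[j - 1], (v[j] - target if j < v.size else math.inf)
        idx = j - 1 if d_lo <= d_hi else j  # tie -> lower wavelength
    dist = abs(v[idx] - target)
    if dist > 0.75 * grid.nominal_step:
        raise RangeError(
            f"{axis_name} {target} nm is {dist:.3g} nm from the nearest grid "
            f"point {v[idx]} nm (> 0.75 x nominal step)"
        )
    return idx


def emission_spectrum_at(eem: EEM, ex_nm: float) -> Spectrum:
    """Emission spectrum at the grid excitation nearest ``ex_nm``.

    Ties snap to the lower wavelength; the returned spectrum's metadata is
    the actual grid wavelength used (query it via the EEM grid if needed).
    """
    i = _nearest_index(eem.ex_grid, ex_nm, "excitation")
    return Spectrum(eem.em_grid, eem.intensity[i].copy(), "emission")


def snapped_excitation(eem: EEM, ex_nm: float) -> float:
    """The actual grid excitation wavelength :func:`emission_spectrum_at` uses."""
    return float(eem.ex_grid.values[_nearest_index(eem.ex_grid, ex_nm, "excitation")])


def excitation_spectrum_at(eem: EEM, em_nm: float) -> Spectrum:
    """Excitation spectrum at the monitored emission nearest ``em_nm``."""
    j = _nearest_index(eem.em_grid, em_nm, "emission")
    return Spectrum(eem.ex_grid, eem.intensity[:, j].copy(), "excitation")


def peak(spectrum: Spectrum) -> tuple[float, float]:
    """(wavelength, intensity) of the maximum; ties go to the lower wavelength."""
    v = spectrum.values
    if np.all(np.isnan(v)):
        raise ValueError("peak of an all-NaN spectrum is undefined")
    idx = int(np.nanargmax(v))  # argmax returns the first (lowest-wavelength) max
    return float(spectrum.wavelengths[idx]), float(v[idx])


def _restrict(spectrum: Spectrum, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid points inside [lo, hi] plus linearly interpolated endpoints."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    x, y = spectrum.wavelengths, spectrum.values
    lo_eff, hi_eff = max(lo, float(x[0])), min(hi, float(x[-1]))
    if lo_eff > hi_eff:
        raise RangeError(
            f"range [{lo}, {hi}] nm does not intersect the grid "
            f"[{x[0]}, {x[-1]}] nm"
        )
    inner = (x > lo_eff) & (x < hi_eff)
    xs = np.concatenate(([lo_eff], x[inner], [hi_eff]))
    ys = np.concatenate(([np.interp(lo_eff, x, y)], y[inner],
                         [np.interp(hi_eff, x, y)]))
    return xs, ys


def auc(spectrum: Spectrum, lo: float = DEFAULT_AUC_RANGE[0],
        hi: float = DEFAULT_AUC_RANGE[1]) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi] nm.

    Partial end intervals are handled by linear interpolation at the
    bounds when they fall inside the grid.
    """
    xs, ys = _restrict(spectrum, lo, hi)
    return float(np.trapezoid(ys, xs))


def centroid(spectrum: Spectrum, lo: float = DEFAULT_AUC_RANGE[0],
             hi: float = DEFAULT_AUC_RANGE[1]) -> float:
    """Equal-area wavelength of the spectrum over [lo, hi] nm.

    The wavelength where the cumulative trapezoidal area first reaches
    half the total, located by linear interpolation of the cumulative-area
    function inside the bracketing interval.  Undefined (ValueError) when
    the total area is not positive.
    """
    xs, ys = _restrict(spectrum, lo, hi)
    cum = cumulative_trapezoid(ys, xs, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("centroid undefined: total area is not positive")
    half = total / 2.0
    k = int(np.argmax(cum >= half))  # first crossing
    if k == 0:
        return float(xs[0])
    denom = cum[k] - cum[k - 1]
    t = 0.0 if denom == 0 else (half - cum[k - 1]) / denom
    return float(xs[k - 1] + t * (xs[k] - xs[k - 1]))


def eem_maxima(eem: EEM) -> tuple[float, float, float]:
    """Global EEM maximum as (excitation nm, emission nm, counts).

    Ties resolve to the lowest excitation wavelength first, then the
    lowest emission wavelength.
    """
    m = eem.intensity
    if np.all(np.isnan(m)):
        raise ValueError("maxima of an all-NaN EEM are undefined")
    top = np.nanmax(m)
    i, j = np.argwhere(m == top)[0]  # row-major order = ex first, then em
    return (float(eem.ex_grid.values[i]), float(eem.em_grid.values[j]), float(top))


def stokes_shift(ex_max_nm: float, em_max_nm: float) -> float:
    """Emission maximum minus excitation maximum, in nm."""
    if not (math.isfinite(ex_max_nm) and math.isfinite(em_max_nm)):
        raise ValueError("Stokes shift requires finite maxima")
    shift = em_max_nm - ex_max_nm
    if shift < 0:
        warnings.warn(
            f"negative Stokes shift ({shift} nm): emission maximum lies "
            "blue of the excitation maximum", stacklevel=2)
    return shift


def quadrature_uncertainty(u_ex: float, u_em: float) -> float:
    """Combine excitation and emission uncertainties in quadrature (nm)."""
    if u_ex < 0 or u_em < 0:
        raise ValueError("uncertainties must be >= 0")
    return math.hypot(u_ex, u_em)


def normalize(spectrum: Spectrum, mode: str = "max",
              reference_value: float | None = None) -> Spectrum:
    """Divide a spectrum by its own maximum or by a shared reference value.

    ``mode='max'`` scales the spectrum to unit peak.  ``mode='reference_value'``
    divides by ``reference_value`` instead, so several spectra normalized by
    one shared reference preserve their relative intensities and AUC ratios.
    """
    if mode == "max":
        norm = float(np.nanmax(spectrum.values))
    elif mode == "reference_value":
        if reference_value is None:
            raise ValueError("reference_value mode requires a reference_value")
        norm = float(reference_value)
    else:
        raise ValueError("mode must be 'max' or 'reference_value'")
    if norm <= 0:
        raise ValueError("normalizer must be > 0")
    return spectrum.replace_values(spectrum.values / norm)


@dataclass(eq=False)
class ExcitationScan:
    """Per-excitation summary rows (peak, intensity, centroid, AUC).

    ``table`` columns: ``excitation_nm, peak_nm, peak_intensity,
    centroid_nm, auc, peak_intensity_ratio, auc_ratio`` — the ratio columns
    are normalized to the scan's maximum so the brightest row prints 1.00.
    """

    table: pd.DataFrame
    auc_range: tuple[float, float]

    @property
    def excitations(self) -> np.ndarray:
        return self.table["excitation_nm"].to_numpy()

    def rows(self) -> list[PeakSummary]:
        return [PeakSummary(r.excitation_nm, r.peak_nm, r.peak_intensity,
                            r.centroid_nm, r.auc)
                for r in self.table.itertuples(index=False)]

    def to_report_table(self) -> pd.DataFrame:
        """Rounded presentation table: wavelengths to 0.5 nm, ratios to 2 dp."""
        t = self.table.copy()
        for col in ("peak_nm", "centroid_nm"):
            t[col] = np.round(t[col] * 2.0) / 2.0
        for col in ("peak_intensity_ratio", "auc_ratio"):
            t[col] = t[col].round(2)
        return t[["excitation_nm", "peak_nm", "peak_intensity_ratio",
                  "centroid_nm", "auc_ratio"]]


def excitation_scan(eem: EEM, excitations, auc_lo: float = DEFAULT_AUC_RANGE[0],
                    auc_hi: float = DEFAULT_AUC_RANGE[1]) -> ExcitationScan:
    """Summarise emission spectra at a list of excitation wavelengths.

    The EEM is expected to be control-subtracted and smoothed already; this
    function only extracts and summarises.  Rows appear in the order the
    excitations are given.
    """
    records = []
    for ex in excitations:
        spec = emission_spectrum_at(eem, float(ex))
        pk_nm, pk_int = peak(spec)
        records.append({
            "excitation_nm": snapped_excitation(eem, float(ex)),
            "peak_nm": pk_nm,
            "peak_intensity": pk_int,
            "centroid_nm": centroid(spec, auc_lo, auc_hi),
            "auc": auc(spec, auc_lo, auc_hi),
        })
    t = pd.DataFrame.from_records(records)
    t["peak_intensity_ratio"] = t["peak_intensity"] / t["peak_intensity"].max()
    t["auc_ratio"] = t["auc"] / t["auc"].max()
    return ExcitationScan(t, (auc_lo, auc_hi))
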