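"""Concentration-series analysis and inner-filter diagnostics.

In optically dilute samples fluorescence intensity grows in proportion to
fluorophore concentration.  As absorbance rises, the excitation beam is
attenuated before it reaches the observation volume (primary inner filter
effect) and emitted photons are re-absorbed on the way out (secondary
inner filter effect), producing intensity roll-off, a concentration-
dependent red shift of the emission peak (CDRS), and divergence between
the measured excitation spectrum and the true absorbance spectrum.

This module quantifies those signatures: the proportional (linear) range
of an intensity-vs-concentration series, the CDRS curve, Beer-Lambert
molar extinction, transmission from optical density, and the
full-width/peak divergence between absorbance and excitation spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EEM, Spectrum
from .metrics import emission_spectrum_at, peak
from .smoothing import SmoothingConfig, rloess

__all__ = [
    "ConcentrationSeries",
    "linear_range",
    "cdrs_curve",
    "molar_extinction",
    "transmission_from_od",
    "spectral_divergence",
    "fwhm",
]


@dataclass(eq=False)
class ConcentrationSeries:
    """Per-concentration emission summaries at one excitation wavelength."""

    concentrations: np.ndarray  # uM, strictly increasing
    max_intensities: np.ndarray  # counts
    peak_wavelengths: np.ndarray  # nm
    normalized_intensities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        i = np.asarray(self.max_intensities, dtype=float)
        p = np.asarray(self.peak_wavelengths, dtype=float)
        if not (c.size == i.size == p.size):
            raise ValueError("series fields must have equal length")
        self.concentrations, self.max_intensities, self.peak_wavelengths = c, i, p
        self.normalized_intensities = i / i.max()

    def __len__(self) -> int:
        return self.concentrations.size


def linear_range(series: ConcentrationSeries, tolerance: float = 0.1
                 ) -> tuple[float, float]:
    """Concentration endpoints of the longest proportional run.

    Consecutive concentration pairs qualify when their log-log slope
    (d log I / d log c) lies within ``tolerance`` of 1, i.e. intensity is
    locally proportional to concentration.  Returns the endpoints of the
    longest contiguous run of qualifying pairs (the earliest run on a
    tie).  Raises ValueError when no pair qualifies.
    """
    if len(series) < 3:
        raise ValueError("linear_range requires >= 3 points")
    c, i = series.concentrations, series.max_intensities
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.diff(np.log(i)) / np.diff(np.log(c))
    ok = np.isfinite(slopes) & (np.abs(slopes - 1.0) <= tolerance)
    best_len, best_start, run_start = 0, -1, None
    for k, good in enumerate(list(ok) + [False]):
        if good and run_start is None:
            run_start = k
        elif not good and run_start is not None:
            if k - run_start > best_len:
                best_len, best_start = k - run_start, run_start
            run_start = None
    if best_len == 0:
        raise ValueError(
            f"no consecutive pair has log-log slope within {tolerance} of 1")
    return float(c[best_start]), float(c[best_start + best_len])


def cdrs_curve(eems: list[EEM], concentrations, ex_nm: float, *,
               smoothing: SmoothingConfig | None = None) -> ConcentrationSeries:
    """Concentration-dependent red shift series at one excitation.

    For each EEM the emission spectrum at ``ex_nm`` is extracted
    (optionally RLOESS-smoothed) and summarised by its peak wavelength and
    maximum intensity; intensities are also reported normalized to the
    series maximum.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size != len(eems):
        raise ValueError("need one concentration per EEM")
    peaks, heights = [], []
    for eem in eems:
        spec = emission_spectrum_at(eem, ex_nm)
        if smoothing is not None:
            spec = rloess(spec, smoothing)
        pk_nm, pk_int = peak(spec)
        peaks.append(pk_nm)
        heights.append(pk_int)
    return ConcentrationSeries(conc, np.asarray(heights), np.asarray(peaks))


def molar_extinction(od: float, conc_um: float, pathlength_cm: float) -> float:
    """Beer-Lambert molar extinction coefficient in L mol^-1 cm^-1.

    ``epsilon = A / (c * l)`` with the concentration given in micromolar.
    """
    if conc_um <= 0 or pathlength_cm <= 0:
        raise ValueError("concentration and pathlength must be > 0")
    if od < 0:
        raise ValueError("optical density must be >= 0")
    return od / (conc_um * 1e-6 * pathlength_cm)


def transmission_from_od(od: float) -> float:
    """Transmitted fraction ``10**(-OD)``."""
    if not np.isfinite(od):
        raise ValueError("OD must be finite")
    return float(10.0 ** (-od))


def fwhm(spectrum: Spectrum) -> float:
    """Full width at half maximum of a unimodal band, in nm.

    Half-maximum crossings on both sides of the peak are located by linear
    interpolation; a ValueError is raised when either side never drops
    below half maximum within the grid.
    """
    x, y = spectrum.wavelengths, spectrum.values
    pk = int(np.nanargmax(y))
    half = y[pk] / 2.0
    left = np.where(y[:pk + 1] < half)[0]
    right = np.where(y[pk:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("half maximum not bracketed on both sides of the peak")
    li = left[-1]  # last sub-half point left of the peak
    xl = np.interp(half, [y[li], y[li + 1]], [x[li], x[li + 1]])
    ri = pk + right[0]  # first sub-half point right of the peak
    xr = np.interp(half, [y[ri], y[ri - 1]], [x[ri], x[ri - 1]])
    return float(xr - xl)


def spectral_divergence(absorbance: Spectrum, excitation: Spectrum) -> dict:
    """Width and peak-position differences between two normalized curves.

    Both spectra are max-normalized; returns ``{"fwhm_diff": nm,
    "peak_diff": nm}`` where a positive ``fwhm_diff`` means the excitation
    spectrum is broader than the absorbance spectrum — the secondary
    inner-filter signature at high concentration.
    """
    w_abs = fwhm(absorbance)
    w_exc = fwhm(excitation)
    pk_abs, _ = peak(absorbance)
    pk_exc, _ = peak(excitation)
    return {"fwhm_diff": float(w_exc - w_abs), "peak_diff": float(pk_exc - pk_abs)}
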