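"""Excitation-dependent emission: red-edge shift quantification.

For an ideal fluorophore obeying the Kasha-Vavilov rule the emission
spectrum is independent of excitation wavelength, so a plot of emission
peak (or centroid) against excitation is flat.  When environmental
relaxation is slow on the fluorescence timescale, exciting at the red edge
of the absorption band photoselects low-energy microstates and the
emission red-shifts with excitation — the red-edge excitation shift
(REES), summarised here as a slope in nm of emission per nm of excitation.
Some media additionally show a non-monotonic local maximum in the curve
below the REES onset, a stronger (anti-Kasha) departure from
excitation-independent behaviour.

The central object is :class:`ExcitationShiftModel`, built from a
peak-vs-excitation or centroid-vs-excitation curve (or directly from an
EEM); its :meth:`~ExcitationShiftModel.fit` returns an
:class:`ExcitationShiftResults` carrying the red-shift slope with its
standard error, the behaviour classification, any detected local bump,
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.signal import find_peaks, peak_prominences

from .core import EEM, subtract_control
from .metrics import (DEFAULT_AUC_RANGE, centroid, emission_spectrum_at, peak,
                      snapped_excitation)
from .smoothing import SmoothingConfig, rloess

__all__ = [
    "ShiftCurve",
    "ShiftAnalysis",
    "shift_curve",
    "red_shift_slope",
    "classify_excitation_dependence",
    "detect_local_bump",
    "ExcitationShiftModel",
    "ExcitationShiftResults",
]

CLASS_INDEPENDENT = "excitation_independent"
CLASS_REES = "rees"
CLASS_ANTI_KASHA = "anti_kasha_non_monotonic"

#: default classification thresholds: a curve whose total range stays within
#: FLAT_TOL nm and whose OLS slope stays within SLOPE_TOL nm/nm is flat.
DEFAULT_FLAT_TOL = 1.0
DEFAULT_SLOPE_TOL = 0.05


@dataclass(frozen=True, eq=False)
class ShiftCurve:
    """Emission peak or centroid as a function of excitation wavelength."""

    excitations: np.ndarray  # nm, strictly increasing
    response: np.ndarray  # nm (peak or centroid wavelength)
    response_kind: str = "peak"  # {peak, centroid}

    def __post_init__(self) -> None:
        x = np.asarray(self.excitations, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if x.size != y.size:
            raise ValueError("excitations and response must have equal length")
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("excitations must be strictly increasing")
        if self.response_kind not in ("peak", "centroid"):
            raise ValueError("response_kind must be 'peak' or 'centroid'")
        object.__setattr__(self, "excitations", x)
        object.__setattr__(self, "response", y)

    def __len__(self) -> int:
        return self.excitations.size


@dataclass(frozen=True)
class ShiftAnalysis:
    """Summary of one red-shift slope fit and its classification."""

    slope: float  # nm per nm of excitation
    method: str  # {endpoint, least_squares}
    fit_range: tuple[float, float]  # nm
    classification: str
    bump: tuple[float, float] | None = None  # (center nm, prominence nm)
    slope_stderr: float | None = None
    intercept: float | None = None


def shift_curve(eem: EEM, response_kind: str = "peak", *,
                ex_lo: float, ex_hi: float, step: float,
                control: EEM | None = None,
                smoothing: SmoothingConfig | None = None,
                auc_lo: float = DEFAULT_AUC_RANGE[0],
                auc_hi: float = DEFAULT_AUC_RANGE[1]) -> ShiftCurve:
    """Build a peak- or centroid-vs-excitation curve from an EEM.

    When ``control``/``smoothing`` are given, each extracted emission
    spectrum is control-subtracted and RLOESS-smoothed before the summary
    metric is computed (row-wise smoothing commutes with row extraction,
    so only the requested rows are smoothed).  At least two excitation
    points are required.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    requested = np.arange(ex_lo, ex_hi + step / 2.0, step)
    if requested.size < 2:
        raise ValueError("shift curve requires at least 2 excitation points")
    sub = subtract_control(eem, control) if control is not None else eem
    xs, ys = [], []
    for ex in requested:
        spec = emission_spectrum_at(sub, float(ex))
        if smoothing is not None:
            spec = rloess(spec, smoothing)
        if response_kind == "peak":
            ys.append(peak(spec)[0])
        elif response_kind == "centroid":
            ys.append(centroid(spec, auc_lo, auc_hi))
        else:
            raise ValueError("response_kind must be 'peak' or 'centroid'")
        xs.append(snapped_excitation(sub, float(ex)))
    return ShiftCurve(np.asarray(xs), np.asarray(ys), response_kind)


def _in_range(curve: ShiftCurve, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    mask = (curve.excitations >= lo - 1e-9) & (curve.excitations <= hi + 1e-9)
    return curve.excitations[mask], curve.response[mask]


def red_shift_slope(curve: ShiftCurve, lo: float, hi: float,
                    method: str = "least_squares") -> float:
    """Red-shift slope (nm emission per nm excitation) over [lo, hi].

    ``endpoint`` divides the response difference between the first and
    last in-range points by their excitation separation; ``least_squares``
    is the ordinary least-squares slope over all in-range points.
    """
    x, y = _in_range(curve, lo, hi)
    if x.size < 2:
        raise ValueError(f"need >= 2 curve points inside [{lo}, {hi}] nm")
    if method == "endpoint":
        return float((y[-1] - y[0]) / (x[-1] - x[0]))
    if method == "least_squares":
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        return float(fit.params[1])
    raise ValueError("method must be 'endpoint' or 'least_squares'")


def classify_excitation_dependence(curve: ShiftCurve,
                                   flat_tol: float = DEFAULT_FLAT_TOL,
                                   slope_tol: float = DEFAULT_SLOPE_TOL) -> str:
    """Classify a shift curve as flat, REES-like, or non-monotonic.

    * ``excitation_independent``: total response range <= ``flat_tol`` nm
      AND |OLS slope| <= ``slope_tol`` nm/nm;
    * ``rees``: otherwise, if the response is non-decreasing to within a
      ``flat_tol`` hysteresis (it never drops more than ``flat_tol`` below
      its running maximum);
    * ``anti_kasha_non_monotonic``: everything else.
    """
    if len(curve) < 5:
        raise ValueError("classification requires >= 5 curve points")
    y = curve.response
    total_range = float(y.max() - y.min())
    slope = red_shift_slope(curve, curve.excitations[0], curve.excitations[-1],
                            "least_squares")
    if total_range <= flat_tol and abs(slope) <= slope_tol:
        return CLASS_INDEPENDENT
    if np.all(y >= np.maximum.accumulate(y) - flat_tol):
        return CLASS_REES
    return CLASS_ANTI_KASHA


def detect_local_bump(curve: ShiftCurve,
                      window: tuple[float, float]) -> tuple[float, float] | None:
    """Find a local maximum of the shift curve inside an excitation window.

    Returns ``(center nm, prominence nm)`` for the tallest interior local
    maximum with positive prominence, or ``None`` when the restricted
    curve is monotone or flat.
    """
    x, y = _in_range(curve, window[0], window[1])
    if x.size < 3:
        return None
    idx, _ = find_peaks(y)
    if idx.size == 0:
        return None
    prom = peak_prominences(y, idx)[0]
    keep = prom > 0
    if not np.any(keep):
        return None
    idx, prom = idx[keep], prom[keep]
    best = int(np.argmax(y[idx]))
    return float(x[idx[best]]), float(prom[best])


class ExcitationShiftModel:
    """Model of emission-vs-excitation behaviour, statsmodels-style.

    Construct from a :class:`ShiftCurve` (or from an EEM with
    :meth:`from_eem`), then call :meth:`fit` to estimate the red-shift
    slope and classify the behaviour.
    """

    def __init__(self, curve: ShiftCurve):
        self.curve = curve

    @classmethod
    def from_eem(cls, eem: EEM, response_kind: str = "peak", *,
                 ex_lo: float, ex_hi: float, step: float,
                 control: EEM | None = None,
                 smoothing: SmoothingConfig | None = None,
                 auc_lo: float = DEFAULT_AUC_RANGE[0],
                 auc_hi: float = DEFAULT_AUC_RANGE[1]) -> "ExcitationShiftModel":
        return cls(shift_curve(eem, response_kind, ex_lo=ex_lo, ex_hi=ex_hi,
                               step=step, control=control, smoothing=smoothing,
                               auc_lo=auc_lo, auc_hi=auc_hi))

    def fit(self, fit_range: tuple[float, float] | None = None,
            method: str = "least_squares",
            flat_tol: float = DEFAULT_FLAT_TOL,
            slope_tol: float = DEFAULT_SLOPE_TOL,
            bump_window: tuple[float, float] | None = None) -> "ExcitationShiftResults":
        """Estimate the red-shift slope over ``fit_range`` and classify.

        ``bump_window`` defaults to all excitations below the fit range,
        so a pre-REES local maximum is not double-counted as part of the
        REES rise.
        """
        curve = self.curve
        lo, hi = fit_range if fit_range is not None else (
            float(curve.excitations[0]), float(curve.excitations[-1]))
        x, y = _in_range(curve, lo, hi)
        if x.size < 2:
            raise ValueError(f"need >= 2 curve points inside [{lo}, {hi}] nm")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        if method == "least_squares":
            slope = float(ols.params[1])
        elif method == "endpoint":
            slope = float((y[-1] - y[0]) / (x[-1] - x[0]))
        else:
            raise ValueError("method must be 'endpoint' or 'least_squares'")
        classification = classify_excitation_dependence(curve, flat_tol, slope_tol)
        if bump_window is None:
            bump_window = (float(curve.excitations[0]), lo)
        bump = None
        if bump_window[1] > bump_window[0]:
            bump = detect_local_bump(curve, bump_window)
        analysis = ShiftAnalysis(
            slope=slope, method=method, fit_range=(lo, hi),
            classification=classification, bump=bump,
            slope_stderr=float(ols.bse[1]), intercept=float(ols.params[0]))
        return ExcitationShiftResults(self, analysis, ols,
                                      flat_tol=flat_tol, slope_tol=slope_tol)


class ExcitationShiftResults:
    """Fit results: slope, uncertainty, classification, diagnostics."""

    def __init__(self, model: ExcitationShiftModel, analysis: ShiftAnalysis,
                 ols_results, *, flat_tol: float, slope_tol: float):
        self.model = model
        self.analysis = analysis
        self._ols = ols_results
        self.flat_tol = flat_tol
        self.slope_tol = slope_tol

    # convenience accessors ------------------------------------------------
    @property
    def slope(self) -> float:
        return self.analysis.slope

    @property
    def slope_stderr(self) -> float | None:
        return self.analysis.slope_stderr

    @property
    def classification(self) -> str:
        return self.analysis.classification

    @property
    def bump(self) -> tuple[float, float] | None:
        return self.analysis.bump

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    def predict(self, excitations) -> np.ndarray:
        """OLS line evaluated at the given excitation wavelengths."""
        x = np.asarray(excitations, dtype=float)
        return self.analysis.intercept + float(self._ols.params[1]) * x

    def summary(self) -> str:
        a = self.analysis
        curve = self.model.curve
        lines = [
            "Excitation-dependence analysis",
            "=" * 46,
            f"response:          {curve.response_kind} wavelength (nm)",
            f"curve points:      {len(curve)} "
            f"({curve.excitations[0]:g}-{curve.excitations[-1]:g} nm)",
            f"fit range:         {a.fit_range[0]:g}-{a.fit_range[1]:g} nm",
            f"slope method:      {a.method}",
            f"red-shift slope:   {a.slope:.4f} nm/nm"
            + (f" (OLS se {a.slope_stderr:.4f})" if a.slope_stderr is not None else ""),
            f"classification:    {a.classification}"
            f"  [flat_tol={self.flat_tol:g} nm, slope_tol={self.slope_tol:g} nm/nm]",
        ]
        if a.bump is not None:
            lines.append(
                f"local bump:        center {a.bump[0]:g} nm, "
                f"prominence {a.bump[1]:.2f} nm")
        else:
            lines.append("local bump:        none detected")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        a = self.analysis
        return {
            "response_kind": self.model.curve.response_kind,
            "excitations_nm": self.model.curve.excitations.tolist(),
            "response_nm": self.model.curve.response.tolist(),
            "fit_range_nm": list(a.fit_range),
            "method": a.method,
            "slope_nm_per_nm": a.slope,
            "slope_stderr": a.slope_stderr,
            "intercept_nm": a.intercept,
            "classification": a.classification,
            "bump": None if a.bump is None else
                    {"center_nm": a.bump[0], "prominence_nm": a.bump[1]},
            "flat_tol_nm": self.flat_tol,
            "slope_tol_nm_per_nm": self.slope_tol,
        }

    def plot(self, ax=None):
        """Quick-look plot of the curve and the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        ax.plot(curve.excitations, curve.response, "o-", label=curve.response_kind)
        lo, hi = self.analysis.fit_range
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, self.predict(xs), "--",
                label=f"OLS slope {self.analysis.slope:.2f} nm/nm")
        ax.set_xlabel("excitation (nm)")
        ax.set_ylabel(f"emission {curve.response_kind} (nm)")
        ax.legend()
        return ax
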