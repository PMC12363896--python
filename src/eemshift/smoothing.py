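"""Robust locally weighted quadratic regression (RLOESS) for spectra.

Scattering media (albumin solutions, printed resin) superimpose a narrow
first-order scattering ridge along the excitation-emission diagonal of an
EEM.  RLOESS removes such narrow outlier features while preserving the
broad fluorescence band: each smoothed value is a locally weighted
2nd-degree polynomial fit, with tricube distance weights multiplied by
bisquare robust weights that are re-estimated from the residuals over a
handful of iterations, driving outlier points to zero influence.

The window is defined in wavelength units (all points within ``span/2`` nm
of the target), not as a point count, so unevenly sampled grids behave
sensibly; on a 0.5 nm emission grid the default 40 nm span covers ~81
points.  Windows become asymmetric near the spectrum edges — no padding or
reflection is used, so no data are invented outside the measured range.

Smoothing of an EEM is applied independently to each emission spectrum
(one excitation row at a time); nothing is smoothed along the excitation
axis, so excitation-axis artifacts such as lamp-correction banding are
deliberately left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EEM, Spectrum
from .exceptions import WindowError

__all__ = ["SmoothingConfig", "rloess", "smooth_eem"]


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the robust local regression.

    span
        Window width in nm (default 40): a point contributes to the fit at
        a target wavelength when it lies within ``span/2`` nm of it.
    robust_iterations
        Number of bisquare re-weighting passes (default 5).
    outlier_cutoff
        Residuals are scaled by ``outlier_cutoff`` times the median
        absolute residual before the bisquare; points beyond that scale
        get zero weight (default 6).
    scale_floor_fraction
        Lower bound on the robust scale, as a fraction of the spectrum's
        amplitude range (default 1e-3).  On noise-free data the median
        absolute residual collapses to the (tiny) local-fit bias and the
        bisquare would treat the entire curved band as outlying; the
        floor keeps robust rejection aimed at genuinely large artifacts
        while leaving noisy data (where the median residual dominates)
        untouched.
    """

    span: float = 40.0
    robust_iterations: int = 5
    outlier_cutoff: float = 6.0
    scale_floor_fraction: float = 1e-3

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("span must be > 0")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")
        if self.outlier_cutoff <= 0:
            raise ValueError("outlier_cutoff must be > 0")
        if self.scale_floor_fraction < 0:
            raise ValueError("scale_floor_fraction must be >= 0")


def _window_slices(x: np.ndarray, half_span: float) -> list[tuple[int, int]]:
    """Per-point [lo, hi) index bounds of the in-span neighbourhood."""
    lo = np.searchsorted(x, x - half_span, side="left")
    hi = np.searchsorted(x, x + half_span, side="right")
    return list(zip(lo.tolist(), hi.tolist()))


def _fit_point(xc: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted quadratic fit value at xc = 0 via least squares."""
    sw = np.sqrt(w)
    design = np.column_stack((np.ones_like(xc), xc, xc * xc))
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    return float(coef[0])


def _smooth_pass(x: np.ndarray, y: np.ndarray,
                 slices: list[tuple[int, int]],
                 robust_w: np.ndarray) -> np.ndarray:
    out = np.empty_like(y)
    for i, (lo, hi) in enumerate(slices):
        xi = x[lo:hi] - x[i]
        yi = y[lo:hi]
        d = np.abs(xi)
        dmax = d.max()
        if dmax > 0:
            tri = (1.0 - (d / dmax) ** 3) ** 3
        else:  # pragma: no cover - needs duplicate wavelengths
            tri = np.ones_like(d)
        w = tri * robust_w[lo:hi]
        if np.count_nonzero(w) < 3:
            # total weight degenerate: fall back to the unweighted local fit
            out[i] = _fit_point(xi, yi, np.ones_like(w))
        else:
            out[i] = _fit_point(xi, yi, w)
    return out


def rloess(spectrum: Spectrum, config: SmoothingConfig | None = None) -> Spectrum:
    """Smooth a spectrum by robust locally weighted quadratic regression.

    Returns a spectrum on the same grid.  Requires at least 7 points, and
    every window must hold at least 3 points (else a :class:`WindowError`
    suggests enlarging the span).
    """
    config = config or SmoothingConfig()
    x = spectrum.wavelengths
    y = spectrum.values
    if x.size < 7:
        raise WindowError("rloess requires at least 7 points")
    slices = _window_slices(x, config.span / 2.0)
    smallest = min(hi - lo for lo, hi in slices)
    if smallest < 3:
        raise WindowError(
            f"a window holds only {smallest} point(s), too few for a local "
            f"quadratic fit; increase span (currently {config.span} nm)"
        )
    robust_w = np.ones_like(y)
    fitted = _smooth_pass(x, y, slices, robust_w)
    floor = config.scale_floor_fraction * np.max(np.abs(y - np.median(y)))
    for _ in range(config.robust_iterations):
        resid = y - fitted
        if np.all(resid == 0):
            break
        scale = config.outlier_cutoff * max(np.median(np.abs(resid)), floor)
        if scale == 0:
            # degenerate scale: any point that deviates at all is an outlier
            robust_w = (resid == 0).astype(float)
        else:
            u = resid / scale
            robust_w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        fitted = _smooth_pass(x, y, slices, robust_w)
    return spectrum.replace_values(fitted)


def smooth_eem(eem: EEM, config: SmoothingConfig | None = None) -> EEM:
    """Apply :func:`rloess` to every excitation row of an EEM.

    Each row (one emission spectrum) is smoothed independently; the
    excitation axis is untouched.
    """
    config = config or SmoothingConfig()
    out = np.empty_like(eem.intensity)
    for i, ex in enumerate(eem.ex_grid.values):
        row = Spectrum(eem.em_grid, eem.intensity[i], "emission")
        try:
            out[i] = rloess(row, config).values
        except WindowError as exc:
            raise WindowError(
                f"smoothing failed at excitation {ex} nm: {exc}"
            ) from exc
    return eem.copy_with(out)
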