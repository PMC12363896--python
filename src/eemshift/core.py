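"""Data model and I/O for excitation-emission matrices (EEMs).

An EEM is a 2-D grid of fluorescence intensity indexed by excitation
wavelength (rows) and emission wavelength (columns): the matrix is a stack
of emission spectra, one per excitation step.  This module provides the
containers (:class:`WavelengthGrid`, :class:`EEM`, :class:`Spectrum`), the
two plain-text CSV dialects used for persistence, and the two acquisition
corrections every downstream analysis assumes: subtraction of a matched
blank (0 uM control) EEM and rescaling to a common integration time.

Conventions
-----------
* Intensities are detector counts (arbitrary units); no radiometric
  calibration is attempted.
* Negative counts are legal *after* control subtraction and are never
  clipped — clipping would bias integrated areas upward in low-signal
  regions.
* Wavelength grids must match exactly (within 1e-6 nm) for subtraction;
  no implicit resampling is performed, because controls are acquired on
  the same instrument grid as their samples.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, GridMismatchError, UnitError

__all__ = [
    "WavelengthGrid",
    "AcquisitionMeta",
    "EEM",
    "Spectrum",
    "SampleDescriptor",
    "GRID_CORNER",
    "read_eem",
    "write_eem",
    "read_spectrum",
    "write_spectrum",
    "subtract_control",
    "rescale_integration",
]

#: literal corner cell of the grid CSV dialect
GRID_CORNER = "ex_nm\\em_nm"

#: tolerance (nm) for deciding two wavelength grids are the same
GRID_TOL = 1e-6

SPECTRUM_KINDS = ("emission", "excitation", "absorbance")


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """A strictly increasing wavelength axis in nm."""

    values: np.ndarray
    step_hint: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 values")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def nominal_step(self) -> float:
        """Nominal spacing in nm (``step_hint`` or the median spacing)."""
        if self.step_hint is not None:
            return float(self.step_hint)
        return float(np.median(np.diff(self.values)))

    def matches(self, other: "WavelengthGrid", tol: float = GRID_TOL) -> bool:
        return len(self) == len(other) and bool(
            np.all(np.abs(self.values - other.values) <= tol)
        )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings needed to compare intensities across samples."""

    integration_time: float = 1.0  # seconds
    accumulations: int = 3
    slit_bandpass: float = 3.0  # nm
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.integration_time <= 0:
            raise ValueError("integration_time must be > 0")
        if self.accumulations < 1:
            raise ValueError("accumulations must be >= 1")


@dataclass(frozen=True)
class SampleDescriptor:
    """Chemical description of a cuvette sample (for Beer-Lambert use)."""

    fluorophore_conc: float  # uM
    medium: str
    cosolute_conc: float | None = None  # mg/mL
    pathlength: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.fluorophore_conc < 0:
            raise ValueError("fluorophore_conc must be >= 0")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")


@dataclass(eq=False)
class Spectrum:
    """A 1-D intensity (or optical-density) trace over wavelength."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"values length {v.size} != grid length {len(self.grid)}"
            )
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}")
        self.values = v

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def replace_values(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, np.asarray(values, dtype=float), self.kind)


@dataclass(eq=False)
class EEM:
    """Excitation-emission matrix: intensity[excitation index, emission index]."""

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensity: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        m = np.asarray(self.intensity, dtype=float)
        expected = (len(self.ex_grid), len(self.em_grid))
        if m.shape != expected:
            raise ValueError(f"intensity shape {m.shape} != {expected}")
        if np.any(np.isnan(m)):
            raise ValueError("intensity contains NaN")
        self.intensity = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy_with(self, intensity: np.ndarray, meta: AcquisitionMeta | None = None) -> "EEM":
        return EEM(self.ex_grid, self.em_grid, np.asarray(intensity, dtype=float),
                   meta if meta is not None else self.meta)


# ---------------------------------------------------------------------------
# I/O — plain-text CSV dialects
# ---------------------------------------------------------------------------

def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell {cell!r} at {where}") from exc


def _check_unique(values: np.ndarray, axis_name: str) -> None:
    uniq, counts = np.unique(values, return_counts=True)
    dupes = uniq[counts > 1]
    if dupes.size:
        raise FormatError(f"duplicate {axis_name} wavelength(s): {dupes.tolist()}")


def _read_grid_dialect(path: Path) -> EEM:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r]  # tolerate trailing blank lines
    if not rows or rows[0][0].strip() != GRID_CORNER:
        got = rows[0][0] if rows and rows[0] else "<empty>"
        raise FormatError(
            f"grid dialect requires corner cell {GRID_CORNER!r}, got {got!r}"
        )
    em = np.array([_parse_float(c, f"header column {j + 2}")
                   for j, c in enumerate(rows[0][1:])])
    if em.size == 0:
        raise FormatError("grid dialect header has no emission wavelengths")
    ex_list, body = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != em.size + 1:
            raise FormatError(
                f"ragged row {i}: expected {em.size + 1} cells, got {len(row)}"
            )
        ex_list.append(_parse_float(row[0], f"row {i}, column 1"))
        body.append([_parse_float(c, f"row {i}, column {j + 2}")
                     for j, c in enumerate(row[1:])])
    ex = np.array(ex_list)
    _check_unique(ex, "excitation")
    _check_unique(em, "emission")
    mat = np.array(body, dtype=float)
    # re-sort axes ascending if the file stored them otherwise
    ex_order = np.argsort(ex)
    em_order = np.argsort(em)
    return EEM(WavelengthGrid(ex[ex_order]), WavelengthGrid(em[em_order]),
               mat[np.ix_(ex_order, em_order)])


def _read_long_dialect(path: Path) -> EEM:
    df = pd.read_csv(path, float_precision="round_trip")
    expected_cols = ["excitation_nm", "emission_nm", "intensity"]
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"long dialect requires header {','.join(expected_cols)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    if df.isna().any().any():
        raise FormatError("long dialect file contains missing/non-numeric values")
    dup = df.duplicated(subset=["excitation_nm", "emission_nm"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["excitation_nm", "emission_nm"]]
        raise FormatError(
            f"duplicate (excitation, emission) pair ({pair.iloc[0]}, {pair.iloc[1]})"
        )
    ex = np.sort(df["excitation_nm"].unique())
    em = np.sort(df["emission_nm"].unique())
    if len(df) != ex.size * em.size:
        have = set(zip(df["excitation_nm"], df["emission_nm"]))
        missing = [(float(a), float(b)) for a in ex for b in em
                   if (a, b) not in have]
        shown = ", ".join(f"({a}, {b})" for a, b in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise FormatError(
            f"long dialect requires a complete excitation x emission "
            f"cross-product; missing pairs: {shown}{more}"
        )
    pivot = df.pivot(index="excitation_nm", columns="emission_nm",
                     values="intensity").sort_index().sort_index(axis=1)
    return EEM(WavelengthGrid(pivot.index.to_numpy(dtype=float)),
               WavelengthGrid(pivot.columns.to_numpy(dtype=float)),
               pivot.to_numpy(dtype=float))


def read_eem(path: str | Path, format: str = "grid") -> EEM:
    """Read an EEM from a CSV file in the ``grid`` or ``long`` dialect.

    Axes are re-sorted to be strictly increasing if the file stores them in
    another order.  Ragged rows, non-numeric cells, duplicate wavelengths
    and (for the long dialect) missing grid cells raise :class:`FormatError`
    naming the offending location.
    """
    path = Path(path)
    if format == "grid":
        return _read_grid_dialect(path)
    if format == "long":
        return _read_long_dialect(path)
    raise ValueError(f"unknown format {format!r}; use 'grid' or 'long'")


def _fmt(value: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return format(float(value), ".17g")


def write_eem(eem: EEM, path: str | Path, format: str = "grid") -> None:
    """Write an EEM to CSV (lossless round-trip with :func:`read_eem`)."""
    path = Path(path)
    if format == "grid":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([GRID_CORNER] + [_fmt(v) for v in eem.em_grid.values])
            for ex, row in zip(eem.ex_grid.values, eem.intensity):
                w.writerow([_fmt(ex)] + [_fmt(v) for v in row])
    elif format == "long":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["excitation_nm", "emission_nm", "intensity"])
            for i, ex in enumerate(eem.ex_grid.values):
                for j, em in enumerate(eem.em_grid.values):
                    w.writerow([_fmt(ex), _fmt(em), _fmt(eem.intensity[i, j])])
    else:
        raise ValueError(f"unknown format {format!r}; use 'grid' or 'long'")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column spectrum CSV with a leading ``# kind=`` comment."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# kind="):
            raise FormatError("spectrum file must start with a '# kind=' line")
        kind = first.split("=", 1)[1].strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["wavelength_nm", "value"]:
        raise FormatError("spectrum header must be 'wavelength_nm,value'")
    if df.isna().any().any():
        raise FormatError("spectrum file contains missing/non-numeric values")
    order = np.argsort(df["wavelength_nm"].to_numpy())
    return Spectrum(WavelengthGrid(df["wavelength_nm"].to_numpy(dtype=float)[order]),
                    df["value"].to_numpy(dtype=float)[order], kind)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# kind={spectrum.kind}\n")
        fh.write("wavelength_nm,value\n")
        for x, y in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{_fmt(x)},{_fmt(y)}\n")


# ---------------------------------------------------------------------------
# Acquisition corrections
# ---------------------------------------------------------------------------

def subtract_control(sample: EEM, control: EEM) -> EEM:
    """Subtract a matched blank (0 uM) EEM from a sample EEM, elementwise.

    Grids must agree to within 1e-6 nm and integration times must already
    be equal (apply :func:`rescale_integration` first if they differ).
    Negative differences are retained.  Metadata is inherited from the
    sample.
    """
    if not sample.ex_grid.matches(control.ex_grid) or not sample.em_grid.matches(control.em_grid):
        raise GridMismatchError(
            "sample and control EEMs must share identical excitation and "
            "emission grids (no implicit resampling is performed)"
        )
    if not np.isclose(sample.meta.integration_time, control.meta.integration_time):
        raise UnitError(
            f"integration times differ (sample {sample.meta.integration_time} s, "
            f"control {control.meta.integration_time} s); rescale_integration first"
        )
    return sample.copy_with(sample.intensity - control.intensity)


def rescale_integration(eem: EEM, reference_time: float) -> EEM:
    """Scale counts linearly to a common integration time.

    A spectrum recorded at half the reference integration time has its
    counts doubled, so intensities remain directly comparable across
    acquisitions.
    """
    if reference_time <= 0:
        raise ValueError("reference_time must be > 0")
    factor = reference_time / eem.meta.integration_time
    meta = dataclasses.replace(eem.meta, integration_time=reference_time)
    return eem.copy_with(eem.intensity * factor, meta)
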