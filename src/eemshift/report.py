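"""End-to-end pipeline orchestration and report tables.

``run_pipeline`` chains the standard processing order — control
subtraction, row-wise RLOESS smoothing, excitation scan, shift analysis —
and writes the smoothed EEM, the scan table, and a JSON shift report that
embeds the exact configuration and seed that produced it, so any report
can be regenerated byte-for-byte from its own provenance block.

``comparison_report`` lays several excitation scans side by side with the
integrated-AUC column normalized to one explicitly chosen (medium,
excitation) reference cell; cross-sample normalization has no silent
default because the convention is sample-specific.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import read_eem, subtract_control, write_eem
from .exceptions import EEMError
from .metrics import ExcitationScan, excitation_scan
from .shift import ExcitationShiftModel
from .smoothing import SmoothingConfig, smooth_eem

__all__ = ["RunConfig", "run_pipeline", "comparison_report"]

log = logging.getLogger("eemshift")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, in one serializable object."""

    input_path: str
    control_path: str | None
    out_dir: str
    eem_format: str = "grid"
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    scan_excitations: tuple[float, ...] = (770.0, 780.0, 790.0, 800.0, 810.0)
    auc_range: tuple[float, float] = (650.0, 1000.0)
    slope_method: str = "least_squares"
    slope_range: tuple[float, float] = (770.0, 810.0)
    shift_step: float = 10.0
    response_kind: str = "peak"
    flat_tol: float = 1.0
    slope_tol: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smoothing"] = dataclasses.asdict(self.smoothing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("smoothing"), dict):
            d["smoothing"] = SmoothingConfig(**d["smoothing"])
        for key in ("scan_excitations", "auc_range", "slope_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name: str, path: str | None, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (EEMError, OSError, ValueError) as exc:
        where = f" ({path})" if path else ""
        raise EEMError(f"pipeline stage '{name}'{where}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run subtract -> smooth -> scan -> shift analysis; write the reports.

    Returns the report bundle as a dict (also written to ``out_dir`` as
    ``smoothed_eem.csv``, ``scan_table.csv`` and ``shift_report.json``).
    Output is deterministic for a fixed config.
    """
    if config.control_path is None:
        raise EEMError("missing required config field 'control_path'")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("reading sample %s", config.input_path)
    sample = _stage("read sample", config.input_path, read_eem,
                    config.input_path, config.eem_format)
    log.info("reading control %s", config.control_path)
    control = _stage("read control", config.control_path, read_eem,
                     config.control_path, config.eem_format)
    net = _stage("control subtraction", config.input_path, subtract_control,
                 sample, control)
    log.info("smoothing (span %.3g nm)", config.smoothing.span)
    smoothed = _stage("smoothing", config.input_path, smooth_eem,
                      net, config.smoothing)
    write_eem(smoothed, out_dir / "smoothed_eem.csv", "grid")

    scan = _stage("excitation scan", None, excitation_scan, smoothed,
                  config.scan_excitations, *config.auc_range)
    scan.to_report_table().to_csv(out_dir / "scan_table.csv", index=False)

    lo, hi = config.slope_range
    model = _stage("shift analysis", None, ExcitationShiftModel.from_eem,
                   smoothed, config.response_kind,
                   ex_lo=lo, ex_hi=hi, step=config.shift_step,
                   auc_lo=config.auc_range[0], auc_hi=config.auc_range[1])
    results = model.fit(fit_range=(lo, hi), method=config.slope_method,
                        flat_tol=config.flat_tol, slope_tol=config.slope_tol)

    bundle = {
        "shift": results.to_dict(),
        "scan_table": scan.to_report_table().to_dict(orient="records"),
        "provenance": {
            "config": config.to_dict(),
            "software_version": __version__,
            "seed": config.seed,
        },
    }
    with open(out_dir / "shift_report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def comparison_report(scans: list[ExcitationScan], labels: list[str],
                      reference: tuple[str, float]) -> pd.DataFrame:
    """Side-by-side scan table across media with shared-reference AUC.

    All scans must cover the same excitation set.  ``reference`` names the
    (label, excitation nm) cell whose AUC becomes 1.0; every AUC in every
    scan is divided by it, so cross-medium brightness ratios are
    preserved.
    """
    if len(scans) != len(labels):
        raise ValueError("need one label per scan")
    base = scans[0].excitations
    for label, scan in zip(labels, scans):
        if scan.excitations.shape != base.shape or not np.allclose(scan.excitations, base):
            raise EEMError(
                f"scan {label!r} covers different excitations than {labels[0]!r}")
    ref_label, ref_ex = reference
    if ref_label not in labels:
        raise ValueError(f"reference label {ref_label!r} not among {labels}")
    ref_scan = scans[labels.index(ref_label)]
    match = np.isclose(ref_scan.excitations, ref_ex)
    if not match.any():
        raise ValueError(f"reference excitation {ref_ex} nm not in the scan")
    ref_auc = float(ref_scan.table.loc[match, "auc"].iloc[0])
    if ref_auc <= 0:
        raise ValueError("reference AUC must be > 0")
    frames = []
    for label, scan in zip(labels, scans):
        t = scan.table[["excitation_nm", "peak_nm", "centroid_nm", "auc"]].copy()
        t["medium"] = label
        t["auc_norm"] = t.pop("auc") / ref_auc
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    return out[["medium", "excitation_nm", "peak_nm", "centroid_nm", "auc_norm"]]
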