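"""Deterministic persistence of runs, sweeps and diagnostics.

A run report consists of:

* ``summary.json`` — parameter echo (SI), topology digest, peak metrics,
  net volumes, validity diagnostics; floats at 9 significant digits with
  sorted keys, so identical runs produce byte-identical files.
* ``timeseries.csv`` — t, nodal pressures, resistor flows and velocities.
* ``topology.yaml`` — the human-readable network description.

Sweep tables are written as plain CSV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .geometries import describe
from .network import NetworkSolution
from .params import ModelParameters, load_parameters
from .resistances import annular_poiseuille_resistance, womersley_number
from .transport import wavelength

__all__ = ["run_report", "write_report", "write_sweep", "params_from_report"]

_SIGNIFICANT_DIGITS = 9


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{_SIGNIFICANT_DIGITS - 1}e}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def validity_diagnostics(params: ModelParameters) -> dict:
    """Model-assumption checks: α, wavelength ratio, b/R_i, resistance swing."""
    pvs, pulse, fluid = params.pvs, params.pulse, params.fluid
    alpha = womersley_number(pvs.inner_radius, pvs.outer_radius,
                             pulse.frequency, fluid.density, fluid.dynamic_viscosity)
    lam, ratio = wavelength(pulse.wave_speed, pulse.frequency, pvs.segment_length)
    R0 = annular_poiseuille_resistance(1.0, 1.0, pvs.outer_radius, pvs.radius_ratio)
    swing = 0.0
    for r in (pvs.inner_radius - pulse.amplitude, pvs.inner_radius + pulse.amplitude):
        if 0 < r < pvs.outer_radius:
            R = annular_poiseuille_resistance(1.0, 1.0, pvs.outer_radius,
                                              r / pvs.outer_radius)
            swing = max(swing, abs(R - R0) / R0)
    return {
        "womersley_alpha": alpha,
        "wavelength_m": lam,
        "wavelength_to_segment_ratio": ratio,
        "amplitude_to_radius_ratio": pulse.amplitude / pvs.inner_radius,
        "resistance_variation_fraction": swing,
    }


def run_report(solution: NetworkSolution, params: ModelParameters,
               metrics: pd.DataFrame | None = None) -> dict:
    """Assemble the full report record for one solved network."""
    report = {
        "parameters": params.to_dict(),
        "topology": describe(solution.network),
        "summary": solution.summary(),
        "diagnostics": validity_diagnostics(params),
    }
    if metrics is not None:
        report["peclet"] = metrics.to_dict(orient="records")
    return report


def write_report(solution: NetworkSolution, params: ModelParameters,
                 out_dir: str | Path, metrics: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write summary.json, timeseries.csv and topology.yaml; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = _round_floats(run_report(solution, params, metrics))
    paths = {
        "summary": out / "summary.json",
        "timeseries": out / "timeseries.csv",
        "topology": out / "topology.yaml",
    }
    paths["summary"].write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    solution.to_frame().to_csv(paths["timeseries"], index=False,
                               float_format=f"%.{_SIGNIFICANT_DIGITS - 1}e",
                               lineterminator="\n")
    paths["topology"].write_text(
        yaml.safe_dump(_round_floats(describe(solution.network)), sort_keys=False)
    )
    return paths


def write_sweep(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False,
                 float_format=f"%.{_SIGNIFICANT_DIGITS - 1}e", lineterminator="\n")
    return path


def params_from_report(summary_path: str | Path) -> ModelParameters:
    """Rebuild the parameter set from a written summary (round-trip)."""
    data = json.loads(Path(summary_path).read_text())
    return load_parameters(data["parameters"])
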