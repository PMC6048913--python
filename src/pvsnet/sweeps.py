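"""Parameter sweeps over the network models.

Every sweep rebuilds the network at each grid point with all non-swept
parameters held at their baseline values, solves one pulse period, and
tabulates peak metrics per element into a tidy table.  Conductivity grids
are logarithmic; amplitude, radius, pulsatility-ratio and phase grids are
linear.

The radii sweep honours the small-gap amplitude rule: the pulse amplitude
is reduced to the largest value for which the free-fluid annulus resistance
stays within a stated tolerance (5% by default) of its mean-radius value
over the whole excursion, so the constant-resistance assumption of the
solver remains valid even for 1 μm gaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometries import (
    TWO_VESSEL_ARTERIAL_PVS,
    TWO_VESSEL_VENOUS_PVS,
    build_network,
)
from .params import ModelParameters, ParameterError
from .resistances import annular_poiseuille_resistance
from .transport import peclet_parenchyma, peclet_pvs

__all__ = [
    "SweepSpec",
    "run_sweep",
    "amplitude_sweep",
    "radii_sweep",
    "conductivity_sweep",
    "pulsatility_ratio_sweep",
    "phase_sweep",
    "max_amplitude_for_resistance_tolerance",
    "NAMED_SWEEPS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepSpec:
    """A named sweep: per-grid-point flat parameter overrides."""

    name: str
    overrides: Sequence[Mapping[str, float]]
    base: ModelParameters = field(default_factory=ModelParameters.baseline)
    porous_pvs: bool = False
    n_samples: int = 256


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Solve every grid point; tidy rows of (grid values, element, peaks, Pe).

    Grid points whose parameters violate an invariant (e.g. R_i ≥ R_o) are
    skipped with a log entry and recorded in ``result.attrs["skipped"]``.
    """
    rows = []
    skipped = []
    for point in spec.overrides:
        try:
            params = spec.base.evolve(**point)
        except ParameterError as exc:
            log.warning("sweep %s: skipping grid point %s (%s)", spec.name, point, exc)
            skipped.append({"point": dict(point), "reason": str(exc)})
            continue
        network = build_network(params, porous_pvs=spec.porous_pvs)
        sol = network.solve_period(spec.n_samples)
        peak_p = sol.peak_pressure()
        for r in network.resistors:
            v = float(np.abs(sol.velocity(r.label)).max())
            if r.element.kind.startswith("annular"):
                pe = peclet_pvs(v, params.conductivities.diffusivity,
                                params.pvs.segment_length)
            else:
                pe = peclet_parenchyma(v, params.conductivities.diffusivity,
                                       params.parenchyma.porosity,
                                       params.parenchyma.vessel_separation)
            rows.append({"sweep": spec.name, **point, "element": r.label,
                         "kind": r.element.kind,
                         "peak_velocity_m_per_s": v,
                         "peak_pressure_Pa": peak_p,
                         "Pe": pe})
    result = pd.DataFrame(rows)
    result.attrs["skipped"] = skipped
    return result


# ---------------------------------------------------------------------------
# the amplitude-vs-resistance-variation rule
# ---------------------------------------------------------------------------


def max_amplitude_for_resistance_tolerance(inner_radius: float, outer_radius: float,
                                           tolerance: float = 0.05) -> float:
    """Largest pulse amplitude keeping the annulus resistance within tolerance.

    Over a pulse cycle the inner radius excursion is [R_i − b, R_i + b]; the
    free-fluid resistance (steady annular Poiseuille) varies with it, most
    steeply as the gap narrows.  Returns the largest b such that the maximum
    relative deviation of the resistance from its value at R_i equals the
    tolerance, found by bracketing root search.
    """
    if not 0 < inner_radius < outer_radius:
        raise ValueError("require 0 < R_i < R_o")
    if not 0 < tolerance < 1:
        raise ValueError("require 0 < tol < 1")
    gap = outer_radius - inner_radius
    # resistance ratio is independent of μ and l; use unit values
    R0 = annular_poiseuille_resistance(1.0, 1.0, outer_radius,
                                       inner_radius / outer_radius)

    def max_deviation(b: float) -> float:
        dev = 0.0
        for r in (inner_radius - b, inner_radius + b):
            R = annular_poiseuille_resistance(1.0, 1.0, outer_radius, r / outer_radius)
            dev = max(dev, abs(R - R0) / R0)
        return dev

    f = lambda b: max_deviation(b) - tolerance
    hi = min(gap, inner_radius) * (1.0 - 1e-9)  # wall may neither close the gap nor cross the axis
    if f(hi) < 0:  # resistance barely varies even at full excursion
        return hi
    return float(brentq(f, 0.0, hi, rtol=1e-12))  # f(0) = −tol < 0


# ---------------------------------------------------------------------------
# named sweeps mirroring the published parameter studies
# ---------------------------------------------------------------------------


def amplitude_sweep(base: ModelParameters | None = None,
                    amplitudes: Sequence[float] | None = None,
                    n_samples: int = 256) -> pd.DataFrame:
    """Pulse amplitude b over its simulated range (0–0.37 μm by default)."""
    base = base or ModelParameters.baseline()
    if amplitudes is None:
        amplitudes = np.linspace(0.0, 0.37e-6, 9)
    spec = SweepSpec("amplitude", [{"b": float(b)} for b in amplitudes],
                     base=base, n_samples=n_samples)
    return run_sweep(spec)


def radii_sweep(base: ModelParameters | None = None,
                pairs: Sequence[tuple[float, float]] | None = None,
                amplitude: float | None = None,
                tolerance: float = 0.05,
                n_samples: int = 256) -> pd.DataFrame:
    """(R_i, R_o) pairs; amplitude reduced per the resistance-variation rule.

    If ``amplitude`` is not given, the sweep uses the smallest admissible
    amplitude across the grid (the tightest-gap pair controls), so a single
    waveform drives every grid point, as in the published radii sweep.
    """
    base = base or ModelParameters.baseline()
    if pairs is None:
        inner = np.array([1e-6, 5e-6, 10e-6, 20e-6, 29e-6])
        outer = np.array([2e-6, 10e-6, 20e-6, 30e-6])
        pairs = [(ri, ro) for ro in outer for ri in inner if ri < ro]
    if amplitude is None:
        amplitude = min(
            max_amplitude_for_resistance_tolerance(ri, ro, tolerance)
            for ri, ro in pairs if ri < ro
        )
    overrides = [{"R_i": float(ri), "R_o": float(ro), "b": float(amplitude)}
                 for ri, ro in pairs]
    spec = SweepSpec("radii", overrides, base=base, n_samples=n_samples)
    out = run_sweep(spec)
    out.attrs["amplitude_m"] = amplitude
    return out


def conductivity_sweep(base: ModelParameters | None = None,
                       which: str = "K_PVS",
                       values: Sequence[float] | None = None,
                       n_samples: int = 256) -> pd.DataFrame:
    """Hydraulic conductivity over 10²–10¹¹ μm³·s/kg (log-spaced).

    ``which="K_PVS"`` sweeps the porous-PVS conductivity (the PVS elements
    switch to their Darcy form); ``which="K"`` sweeps the parenchyma
    conductivity with the PVS kept a free-fluid annulus.
    """
    base = base or ModelParameters.baseline()
    if which not in ("K_PVS", "K"):
        raise ValueError("which must be 'K_PVS' or 'K'")
    if values is None:
        values = np.logspace(-16, -7, 10)  # SI for 1e2–1e11 μm³·s/kg
    spec = SweepSpec(f"conductivity_{which}", [{which: float(v)} for v in values],
                     base=base, porous_pvs=(which == "K_PVS"), n_samples=n_samples)
    return run_sweep(spec)


def pulsatility_ratio_sweep(base: ModelParameters | None = None,
                            ratios: Sequence[float] | None = None,
                            n_samples: int = 256) -> pd.DataFrame:
    """Venous:arterial pulsatility ratio ξ over [0, 1] (two-vessel model)."""
    base = (base or ModelParameters.baseline()).evolve(variant="two_vessel")
    if ratios is None:
        ratios = np.linspace(0.0, 1.0, 6)
    spec = SweepSpec("pulsatility_ratio", [{"xi": float(x)} for x in ratios],
                     base=base, n_samples=n_samples)
    return run_sweep(spec)


def phase_sweep(base: ModelParameters | None = None,
                phases: Sequence[float] | None = None,
                n_samples: int = 256) -> pd.DataFrame:
    """Venous phase delay θ over [0, 2π) in the two-vessel model.

    Signed velocities are sampled a quarter period into the arterial
    waveform (the arterial source maximum), for representative elements:
    the arterial and venous PVS boundary elements (R1, R4), the parenchyma
    element perpendicular to the vessels in the 50–150 μm band (R13), and a
    parallel element of the 50 μm grid column (R9).  Peak magnitudes over
    the period are reported alongside.
    """
    base = (base or ModelParameters.baseline()).evolve(variant="two_vessel")
    if phases is None:
        phases = np.linspace(0.0, 2.0 * math.pi, 9, endpoint=False)
    if n_samples % 4:
        raise ValueError("n_samples must be divisible by 4 for the T/4 sample")
    rows = []
    for theta in phases:
        params = base.evolve(theta=float(theta))
        sol = build_network(params).solve_period(n_samples)
        t_quarter = sol.period / 4.0
        rows.append({
            "theta": float(theta),
            "v_arterial_pvs_m_per_s": sol.velocity_at("R1", t_quarter),
            "v_venous_pvs_m_per_s": sol.velocity_at("R4", t_quarter),
            "v_parenchyma_perpendicular_m_per_s": sol.velocity_at("R13", t_quarter),
            "v_parenchyma_parallel_m_per_s": sol.velocity_at("R9", t_quarter),
            "peak_arterial_pvs_m_per_s": sol.peak_velocity(TWO_VESSEL_ARTERIAL_PVS),
            "peak_venous_pvs_m_per_s": sol.peak_velocity(TWO_VESSEL_VENOUS_PVS),
            "peak_pressure_Pa": sol.peak_pressure(),
        })
    out = pd.DataFrame(rows)
    out.attrs["sampled_at"] = "T/4 of the arterial waveform"
    return out


#: Sweeps runnable by name from the command line.
NAMED_SWEEPS = {
    "amplitude": amplitude_sweep,
    "radii": radii_sweep,
    "conductivity_pvs": lambda base=None, n_samples=256: conductivity_sweep(
        base, which="K_PVS", n_samples=n_samples),
    "conductivity_parenchyma": lambda base=None, n_samples=256: conductivity_sweep(
        base, which="K", n_samples=n_samples),
    "pulsatility_ratio": pulsatility_ratio_sweep,
    "phase": phase_sweep,
}
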