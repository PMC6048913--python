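"""Physical parameters of the perivascular-flow network models.

All quantities are stored internally in canonical SI units (m, s, kg, Pa).
Printed values in the physiology literature mix μm, nm, Hz, mPa·s and the
two equivalent hydraulic-conductivity spellings m³·s/kg and m²/(Pa·s)
(plus the μm³·s/kg variant, 10⁻¹⁸ of the SI value); everything is converted
at the boundary so the physics code never sees a non-SI number.

The default values are the baseline parameter set for a penetrating
arteriole segment in rat cortex: a 10 μm vessel radius inside a 30 μm
perivascular annulus, a 300 μm segment length, a 0.25 μm sinusoidal wall
pulse at 5 Hz, and a parenchyma (brain tissue) hydraulic conductivity of
5.63 × 10⁻¹² m²/(Pa·s).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "FluidProperties",
    "PVSGeometry",
    "ParenchymaGeometry",
    "PulseParameters",
    "Conductivities",
    "ModelParameters",
    "ParameterError",
    "convert_conductivity",
    "parse_quantity",
    "load_parameters",
]


class ParameterError(ValueError):
    """Raised with the aggregated list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


# ---------------------------------------------------------------------------
# unit handling (only the units the source literature actually uses)
# ---------------------------------------------------------------------------

_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6, "nm": 1e-9}
_FREQUENCY = {"Hz": 1.0, "1/s": 1.0}
_TIME = {"s": 1.0, "ms": 1e-3}
_SPEED = {"m/s": 1.0, "cm/s": 1e-2, "um/s": 1e-6, "μm/s": 1e-6}
_VISCOSITY = {"Pa s": 1.0, "Pa·s": 1.0, "Pa.s": 1.0, "mPa s": 1e-3, "mPa·s": 1e-3}
_DENSITY = {"kg/m^3": 1.0, "kg/m3": 1.0, "kg/m³": 1.0}
_DIFFUSIVITY = {"m^2/s": 1.0, "m2/s": 1.0, "um^2/s": 1e-12, "μm^2/s": 1e-12, "um2/s": 1e-12}
_PRESSURE = {"Pa": 1.0, "mPa": 1e-3, "mmHg": 133.322387415}
_ANGLE = {"rad": 1.0, "deg": math.pi / 180.0}
_DIMLESS = {"": 1.0, "-": 1.0}

#: Hydraulic conductivity: m³·s/kg and m²/(Pa·s) are dimensionally identical
#: (Pa = kg·m⁻¹·s⁻²); μm³·s/kg carries a 10⁻¹⁸ scale factor.
_CONDUCTIVITY = {
    "m^3 s/kg": 1.0,
    "m^3·s/kg": 1.0,
    "m3 s/kg": 1.0,
    "m³·s/kg": 1.0,
    "m^2/(Pa s)": 1.0,
    "m^2/(Pa·s)": 1.0,
    "m2/(Pa s)": 1.0,
    "m²/(Pa·s)": 1.0,
    "um^3 s/kg": 1e-18,
    "um^3·s/kg": 1e-18,
    "um3 s/kg": 1e-18,
    "μm^3 s/kg": 1e-18,
    "μm³·s/kg": 1e-18,
}

_DIMENSIONS = {
    "length": _LENGTH,
    "frequency": _FREQUENCY,
    "time": _TIME,
    "speed": _SPEED,
    "viscosity": _VISCOSITY,
    "density": _DENSITY,
    "diffusivity": _DIFFUSIVITY,
    "pressure": _PRESSURE,
    "angle": _ANGLE,
    "dimensionless": _DIMLESS,
    "conductivity": _CONDUCTIVITY,
}


def parse_quantity(value: Any, dimension: str) -> float:
    """Convert ``value`` to SI for the given dimension.

    Numbers are assumed to already be SI.  Strings must be of the form
    ``"<number> <unit>"`` (e.g. ``"10 um"``, ``"5.63e6 um^3 s/kg"``) with a
    unit recognised for that dimension.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split(None, 1)
        if not parts:
            raise ValueError("empty quantity string")
        try:
            number = float(parts[0])
        except ValueError as exc:
            raise ValueError(f"cannot parse number in {value!r}") from exc
        unit = parts[1].strip() if len(parts) > 1 else ""
        table = _DIMENSIONS[dimension]
        if unit not in table:
            raise ValueError(
                f"unrecognized {dimension} unit {unit!r} "
                f"(known: {', '.join(sorted(u for u in table if u))})"
            )
        return number * table[unit]
    raise ValueError(f"cannot interpret {value!r} as a quantity")


def convert_conductivity(value: float, unit: str) -> float:
    """Convert a hydraulic conductivity to SI (m³·s/kg ≡ m²/(Pa·s)).

    >>> convert_conductivity(5.63e6, "um^3 s/kg")
    5.63e-12
    """
    if unit not in _CONDUCTIVITY:
        raise ValueError(f"unrecognized conductivity unit {unit!r}")
    return value * _CONDUCTIVITY[unit]


# ---------------------------------------------------------------------------
# parameter groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Interstitial fluid: close to water at body temperature."""

    dynamic_viscosity: float = 0.9e-3  # μ, Pa·s
    density: float = 993.2  # ρ, kg/m³

    def problems(self) -> list[str]:
        out = []
        if not self.dynamic_viscosity > 0:
            out.append("dynamic_viscosity must be > 0 (μ > 0)")
        if not self.density > 0:
            out.append("density must be > 0 (ρ > 0)")
        return out


@dataclass(frozen=True)
class PVSGeometry:
    """Annular perivascular space around a vessel segment."""

    inner_radius: float = 10e-6  # R_i, time-averaged, m
    outer_radius: float = 30e-6  # R_o, m
    segment_length: float = 300e-6  # L_PVS, m

    @property
    def radius_ratio(self) -> float:
        """E = R_i / R_o."""
        return self.inner_radius / self.outer_radius

    @property
    def gap(self) -> float:
        """Annular gap thickness R_o − R_i."""
        return self.outer_radius - self.inner_radius

    def problems(self) -> list[str]:
        out = []
        if not 0 < self.inner_radius:
            out.append("PVS inner_radius must be > 0 (R_i > 0)")
        if not self.inner_radius < self.outer_radius:
            out.append("PVS radii must satisfy 0 < R_i < R_o")
        if not self.segment_length > 0:
            out.append("PVS segment_length must be > 0 (L_PVS > 0)")
        return out


@dataclass(frozen=True)
class ParenchymaGeometry:
    """Brain tissue surrounding the PVS, treated as a rigid porous medium."""

    inner_radius: float = 10e-6  # R_i^PCY, m
    outer_radius: float = 300e-6  # R_o^PCY, m
    shell_height: float = 100e-6  # h, m
    slab_depth: float = 200e-6  # d, m
    vessel_separation: float = 200e-6  # L_PCY, m
    porosity: float = 0.2  # ϕ
    pore_size: float = 60e-9  # η, m

    def problems(self) -> list[str]:
        out = []
        if not 0 < self.inner_radius < self.outer_radius:
            out.append("parenchyma radii must satisfy 0 < R_i^PCY < R_o^PCY")
        for name in ("shell_height", "slab_depth", "vessel_separation", "pore_size"):
            if not getattr(self, name) > 0:
                out.append(f"parenchyma {name} must be > 0")
        if not 0 < self.porosity < 1:
            out.append("porosity must satisfy 0 < ϕ < 1")
        return out


@dataclass(frozen=True)
class PulseParameters:
    """Sinusoidal vessel-wall motion: r_i(t) = R_i − b·cos(2πft − θ)."""

    amplitude: float = 0.25e-6  # b, m
    frequency: float = 5.0  # f, Hz
    wave_speed: float = 1.0  # m/s
    phase_shift: float = 0.0  # θ, rad (venous delay in the two-vessel model)
    pulsatility_ratio: float = 0.80  # ξ, venous:arterial
    measurement_interval: float | None = None  # T, s; defaults to one period

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def interval(self) -> float:
        """T in the pulsatility integral; one pulse period unless overridden."""
        return self.measurement_interval if self.measurement_interval else self.period

    def problems(self) -> list[str]:
        out = []
        if self.amplitude < 0:
            out.append("pulse amplitude must satisfy b ≥ 0")
        if not self.frequency > 0:
            out.append("pulse frequency must satisfy f > 0")
        if not self.wave_speed > 0:
            out.append("wave_speed must be > 0")
        if not 0 <= self.pulsatility_ratio <= 1:
            out.append("pulsatility_ratio must satisfy 0 ≤ ξ ≤ 1")
        if not 0 <= self.phase_shift < 2 * math.pi:
            out.append("phase_shift must satisfy θ ∈ [0, 2π)")
        if self.measurement_interval is not None and not self.measurement_interval > 0:
            out.append("measurement_interval must be > 0")
        return out


@dataclass(frozen=True)
class Conductivities:
    """Hydraulic conductivities (m³·s/kg ≡ m²/(Pa·s)) and solute diffusivity."""

    parenchyma: float = 5.63e-12  # K_PCY
    pvs: float = 5.63e-12  # K_PVS, used only by the porous-PVS variant
    diffusivity: float = 1e-10  # D*, m²/s (mid-range of 10–10³ μm²/s)

    def problems(self) -> list[str]:
        out = []
        for name in ("parenchyma", "pvs", "diffusivity"):
            if not getattr(self, name) > 0:
                out.append(f"conductivity {name} must be > 0")
        return out


_VARIANTS = ("one_vessel", "two_vessel")


@dataclass(frozen=True)
class ModelParameters:
    """Full validated parameter set for either network variant."""

    fluid: FluidProperties = field(default_factory=FluidProperties)
    pvs: PVSGeometry = field(default_factory=PVSGeometry)
    parenchyma: ParenchymaGeometry = field(default_factory=ParenchymaGeometry)
    pulse: PulseParameters = field(default_factory=PulseParameters)
    conductivities: Conductivities = field(default_factory=Conductivities)
    variant: str = "one_vessel"

    def __post_init__(self):
        problems = self.problems()
        if problems:
            raise ParameterError(problems)

    def problems(self) -> list[str]:
        out: list[str] = []
        for group in (self.fluid, self.pvs, self.parenchyma, self.pulse, self.conductivities):
            out.extend(group.problems())
        if self.variant not in _VARIANTS:
            out.append(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.pulse.amplitude >= self.pvs.inner_radius:
            out.append("pulse amplitude must satisfy b < R_i (wall cannot cross the axis)")
        return out

    # -- flat Table-style key access -------------------------------------

    def evolve(self, **flat: Any) -> "ModelParameters":
        """Return a copy with flat symbol keys (``R_i``, ``b`` ...) replaced."""
        data = self.to_dict()
        data.update(flat)
        return ModelParameters.from_dict(data)

    def to_dict(self) -> dict[str, float | str]:
        """Flat symbol → SI value mapping (round-trips through from_dict)."""
        out: dict[str, float | str] = {}
        for key, (group, attr, _dim) in _KEYS.items():
            if key in _ALIASES:
                continue
            value = getattr(getattr(self, group), attr)
            if value is not None:
                out[key] = value
        out["variant"] = self.variant
        return out

    @staticmethod
    def from_dict(config: Mapping[str, Any]) -> "ModelParameters":
        return _from_flat(config)

    @staticmethod
    def baseline(variant: str = "one_vessel") -> "ModelParameters":
        return ModelParameters(variant=variant)


#: flat config key → (parameter group attribute, field, dimension)
_KEYS: dict[str, tuple[str, str, str]] = {
    "R_i": ("pvs", "inner_radius", "length"),
    "R_o": ("pvs", "outer_radius", "length"),
    "L_PVS": ("pvs", "segment_length", "length"),
    "L_PCY": ("parenchyma", "vessel_separation", "length"),
    "b": ("pulse", "amplitude", "length"),
    "f": ("pulse", "frequency", "frequency"),
    "wave_speed": ("pulse", "wave_speed", "speed"),
    "theta": ("pulse", "phase_shift", "angle"),
    "xi": ("pulse", "pulsatility_ratio", "dimensionless"),
    "T": ("pulse", "measurement_interval", "time"),
    "K": ("conductivities", "parenchyma", "conductivity"),
    "K_PCY": ("conductivities", "parenchyma", "conductivity"),
    "K_PVS": ("conductivities", "pvs", "conductivity"),
    "D_star": ("conductivities", "diffusivity", "diffusivity"),
    "mu": ("fluid", "dynamic_viscosity", "viscosity"),
    "rho": ("fluid", "density", "density"),
    "phi": ("parenchyma", "porosity", "dimensionless"),
    "h": ("parenchyma", "shell_height", "length"),
    "d": ("parenchyma", "slab_depth", "length"),
    "R_i_PCY": ("parenchyma", "inner_radius", "length"),
    "R_o_PCY": ("parenchyma", "outer_radius", "length"),
    "eta": ("parenchyma", "pore_size", "length"),
}
_ALIASES = {"K_PCY"}  # same storage as "K"


def _from_flat(config: Mapping[str, Any]) -> ModelParameters:
    groups: dict[str, dict[str, float]] = {
        "fluid": {}, "pvs": {}, "parenchyma": {}, "pulse": {}, "conductivities": {}
    }
    variant = "one_vessel"
    problems: list[str] = []
    for key, raw in config.items():
        if key in ("variant", "model"):
            variant = str(raw)
            continue
        if key not in _KEYS:
            problems.append(f"unknown parameter key {key!r}")
            continue
        group, attr, dim = _KEYS[key]
        try:
            groups[group][attr] = parse_quantity(raw, dim)
        except ValueError as exc:
            problems.append(f"{key}: {exc}")
    if problems:
        raise ParameterError(problems)
    try:
        return ModelParameters(
            fluid=FluidProperties(**groups["fluid"]),
            pvs=PVSGeometry(**groups["pvs"]),
            parenchyma=ParenchymaGeometry(**groups["parenchyma"]),
            pulse=PulseParameters(**groups["pulse"]),
            conductivities=Conductivities(**groups["conductivities"]),
            variant=variant,
        )
    except ParameterError:
        raise


def load_parameters(source: str | Path | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build :class:`ModelParameters` from a YAML file, mapping, or nothing.

    Keys follow the conventional symbols (``R_i``, ``R_o``, ``b``, ``f``,
    ``K``, ...).  Values are SI numbers or ``"<number> <unit>"`` strings.
    Unspecified keys take their baseline defaults.  All validation errors
    are aggregated into a single :class:`ParameterError`.
    """
    if source is None:
        return ModelParameters.baseline()
    if isinstance(source, Mapping):
        return _from_flat(source)
    text = Path(source).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ParameterError([f"config root must be a mapping, got {type(data).__name__}"])
    return _from_flat(data)
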