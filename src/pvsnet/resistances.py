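"""Hydraulic resistance of the network elements.

Four element kinds appear in the models:

``annular_free``
    Steady pressure-driven (Poiseuille) flow through a straight annulus,
    R = 8μl / (π R_o⁴ [1 − E⁴ + (E² − 1)²/ln E]) with E = R_i/R_o.
``annular_porous``
    Darcy axial flow through an annulus of rigid porous media,
    R = l / (π (R_o² − R_i²) K).
``radial_shell``
    One-dimensional radial Darcy flow through a cylindrical tissue shell,
    R = ln(R_o/R_i) / (2π h K).
``darcy_slab``
    Rectangular Darcy element of length l, height h and depth d,
    R = l / (K h d), used for the planar parenchyma grid between vessels.

Resistances are in Pa·s/m³.  Each element also carries the cross-sectional
area used to convert a volumetric flow rate into a reported fluid velocity.
Half-annulus elements (the two-vessel model resolves only the half of each
PVS facing the modeled tissue slab) double the full-annulus resistance; their
velocity-conversion area is kept at the *full* annular cross-section — see
the methods note for why this convention is the one consistent with the
model's reported velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .params import ModelParameters

__all__ = [
    "ResistanceElement",
    "annular_poiseuille_resistance",
    "porous_annulus_resistance",
    "radial_shell_resistance",
    "darcy_slab_resistance",
    "annular_area",
    "womersley_number",
    "free_annulus_element",
    "porous_annulus_element",
    "radial_shell_element",
    "darcy_slab_element",
]


def annular_poiseuille_resistance(mu: float, length: float, outer_radius: float,
                                  radius_ratio: float) -> float:
    """Free-fluid annulus resistance for steady axial Poiseuille flow.

    ``radius_ratio`` is E = R_i/R_o and must lie strictly in (0, 1);
    at E → 0 the expression reduces to the Hagen–Poiseuille pipe value
    8μl/(πR_o⁴).
    """
    if not 0 < radius_ratio < 1:
        raise ValueError(f"radius ratio E must be in (0, 1), got {radius_ratio}")
    if mu <= 0 or outer_radius <= 0 or length < 0:
        raise ValueError("require μ > 0, R_o > 0, l ≥ 0")
    E = radius_ratio
    bracket = 1.0 - E**4 + (E**2 - 1.0) ** 2 / math.log(E)
    if bracket <= 0:
        raise ValueError(f"degenerate annulus: bracket term {bracket} ≤ 0")
    return 8.0 * mu * length / (math.pi * outer_radius**4 * bracket)


def porous_annulus_resistance(K: float, length: float, inner_radius: float,
                              outer_radius: float) -> float:
    """Darcy resistance of an annulus of rigid porous media (axial flow)."""
    if outer_radius <= inner_radius or inner_radius < 0:
        raise ValueError("require R_o > R_i ≥ 0")
    if K <= 0 or length < 0:
        raise ValueError("require K > 0 and l ≥ 0")
    return length / (math.pi * (outer_radius**2 - inner_radius**2) * K)


def radial_shell_resistance(K: float, height: float, inner_radius: float,
                            outer_radius: float) -> float:
    """Darcy resistance of radial flow through a cylindrical shell."""
    if not 0 < inner_radius <= outer_radius:
        raise ValueError("require 0 < R_i^PCY ≤ R_o^PCY")
    if K <= 0 or height <= 0:
        raise ValueError("require K > 0 and h > 0")
    return math.log(outer_radius / inner_radius) / (2.0 * math.pi * height * K)


def darcy_slab_resistance(K: float, length: float, height: float, depth: float) -> float:
    """Darcy resistance of a rectangular slab (flow along ``length``)."""
    if K <= 0 or height <= 0 or depth <= 0 or length < 0:
        raise ValueError("require K, h, d > 0 and l ≥ 0")
    return length / (K * height * depth)


def annular_area(inner_radius: float, outer_radius: float) -> float:
    """Cross-sectional area of the full annulus π(R_o² − R_i²)."""
    return math.pi * (outer_radius**2 - inner_radius**2)


def womersley_number(inner_radius: float, outer_radius: float, frequency: float,
                     density: float, viscosity: float) -> float:
    """α = 2(R_o − R_i)·sqrt(2πfρ/μ).

    Twice the gap is the hydrodynamic radius of the annulus; α ≪ 1 means
    oscillatory flow is well approximated by the quasi-steady profile of the
    instantaneous pressure gradient.
    """
    if outer_radius <= inner_radius:
        raise ValueError("require R_o > R_i")
    if density <= 0 or viscosity <= 0 or frequency < 0:
        raise ValueError("require ρ, μ > 0 and f ≥ 0")
    return 2.0 * (outer_radius - inner_radius) * math.sqrt(
        2.0 * math.pi * frequency * density / viscosity
    )


@dataclass(frozen=True)
class ResistanceElement:
    """A network resistor with its geometry-derived resistance and areas.

    ``area`` is the velocity-conversion cross-section; ``geometry`` keeps the
    raw dimensions so radial-shell velocities can be re-evaluated at any
    radius inside the shell.
    """

    kind: str  # annular_free | annular_porous | radial_shell | darcy_slab
    resistance: float  # Pa·s/m³
    area: float  # m², default velocity-conversion area
    length: float = float("nan")  # m, axial/flow length (nan for shells)
    half_annulus: bool = False
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.resistance >= 0:
            raise ValueError(f"resistance must be ≥ 0, got {self.resistance}")
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")

    def velocity_area(self, radius: Optional[float] = None) -> float:
        """Area converting flow to velocity, optionally at a shell radius.

        For ``radial_shell`` elements the flow crosses cylindrical surfaces
        2πrh; callers may evaluate the superficial (Darcy) velocity at any
        radius within the shell.  Other kinds ignore ``radius``.
        """
        if radius is None or self.kind != "radial_shell":
            return self.area
        r_in = self.geometry["inner_radius"]
        r_out = self.geometry["outer_radius"]
        if not r_in <= radius <= r_out:
            raise ValueError(
                f"evaluation radius {radius} outside shell [{r_in}, {r_out}]"
            )
        return 2.0 * math.pi * radius * self.geometry["height"]


# ---------------------------------------------------------------------------
# element constructors from a validated parameter set
# ---------------------------------------------------------------------------


def free_annulus_element(params: ModelParameters, length: float,
                         half: bool = False) -> ResistanceElement:
    """Free-fluid PVS element; ``half=True`` doubles R (half annulus)."""
    pvs = params.pvs
    R = annular_poiseuille_resistance(
        params.fluid.dynamic_viscosity, length, pvs.outer_radius, pvs.radius_ratio
    )
    if half:
        R *= 2.0
    return ResistanceElement(
        kind="annular_free",
        resistance=R,
        area=annular_area(pvs.inner_radius, pvs.outer_radius),
        length=length,
        half_annulus=half,
        geometry={"inner_radius": pvs.inner_radius, "outer_radius": pvs.outer_radius},
    )


def porous_annulus_element(params: ModelParameters, length: float,
                           half: bool = False) -> ResistanceElement:
    """Porous-media PVS element; ``half=True`` doubles R (half annulus)."""
    pvs = params.pvs
    R = porous_annulus_resistance(
        params.conductivities.pvs, length, pvs.inner_radius, pvs.outer_radius
    )
    if half:
        R *= 2.0
    return ResistanceElement(
        kind="annular_porous",
        resistance=R,
        area=annular_area(pvs.inner_radius, pvs.outer_radius),
        length=length,
        half_annulus=half,
        geometry={"inner_radius": pvs.inner_radius, "outer_radius": pvs.outer_radius},
    )


def radial_shell_element(params: ModelParameters,
                         eval_radius: Optional[float] = None) -> ResistanceElement:
    """Radial parenchyma shell; default velocity area 2πrh at ``eval_radius``.

    The default evaluation radius is the PVS outer radius, i.e. velocities
    are reported where tissue meets the perivascular annulus.
    """
    pcy = params.parenchyma
    R = radial_shell_resistance(
        params.conductivities.parenchyma, pcy.shell_height,
        pcy.inner_radius, pcy.outer_radius,
    )
    r_eval = params.pvs.outer_radius if eval_radius is None else eval_radius
    if not pcy.inner_radius <= r_eval <= pcy.outer_radius:
        raise ValueError("evaluation radius outside the parenchyma shell")
    return ResistanceElement(
        kind="radial_shell",
        resistance=R,
        area=2.0 * math.pi * r_eval * pcy.shell_height,
        geometry={
            "inner_radius": pcy.inner_radius,
            "outer_radius": pcy.outer_radius,
            "height": pcy.shell_height,
        },
    )


def darcy_slab_element(params: ModelParameters, length: float) -> ResistanceElement:
    """Rectangular parenchyma grid element (two-vessel model)."""
    pcy = params.parenchyma
    R = darcy_slab_resistance(
        params.conductivities.parenchyma, length, pcy.shell_height, pcy.slab_depth
    )
    return ResistanceElement(
        kind="darcy_slab",
        resistance=R,
        area=pcy.shell_height * pcy.slab_depth,
        length=length,
        geometry={"height": pcy.shell_height, "depth": pcy.slab_depth},
    )
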