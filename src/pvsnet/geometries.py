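"""Builders for the one-vessel and two-vessel network layouts.

One-vessel model (7 resistors, 3 sources)
-----------------------------------------
A 300 μm arteriole segment.  The annular PVS is an axial resistor chain
R1(50 μm)–R2(100)–R3(100)–R4(50) whose ends are grounded (fluid exits
axially into unmodeled PVS); the three interior nodes n1–n3 each carry a
pulsatile source (IA1–IA3, 100 μm of vessel each) and a radial cylindrical
tissue shell (R5–R7) to ground (fluid exits radially into far parenchyma).

Two-vessel model (25 resistors, 6 sources)
------------------------------------------
A planar slab of tissue containing an arteriole and a vein 200 μm apart.
Only the half of each PVS facing the slab is resolved: half-annulus PVS
elements carry twice the full-annulus resistance, and the sources carry
the half-annulus geometry factor 2π².  Between the vessels a rectangular
Darcy grid discretizes the parenchyma with two node columns at 50 and
150 μm from the arterial PVS; rows sit at the three source nodes and the
grid is grounded at the top and bottom tissue boundaries.

Resistors are numbered in row-major reading order of the planar layout:

    row 0 (top boundary):   R1 (PVS-a) R2 (x)   R3 (y)   R4 (PVS-v)
    row 1 (horizontal):     R5  R6  R7
    rows 1–2 (vertical):    R8 (PVS-a) R9 (x)   R10 (y)  R11 (PVS-v)
    row 2 (horizontal):     R12 R13 R14
    rows 2–3 (vertical):    R15 (PVS-a) R16 (x) R17 (y)  R18 (PVS-v)
    row 3 (horizontal):     R19 R20 R21
    row 4 (bottom boundary):R22 (PVS-a) R23 (x) R24 (y)  R25 (PVS-v)

which reproduces the canonical assignment of 100 μm lengths to
R6, R8, R9, R10, R11, R13, R15, R16, R17, R18 and R20 (all other elements
are 50 μm): vertical elements span the 100 μm between source rows, the
middle horizontal elements span the 100 μm between the two grid columns,
and every boundary-adjacent element spans 50 μm.
"""

from __future__ import annotations

from typing import Callable

from .network import GROUND, HydraulicNetwork, Resistor, SourceAttachment
from .params import ModelParameters
from .resistances import (
    ResistanceElement,
    darcy_slab_element,
    free_annulus_element,
    porous_annulus_element,
    radial_shell_element,
)
from .sources import (
    FULL_VESSEL_FACTOR,
    HALF_VESSEL_FACTOR,
    PulsatileSource,
    venous_amplitude,
)

__all__ = [
    "build_one_vessel",
    "build_two_vessel",
    "build_network",
    "describe",
    "ONE_VESSEL_PVS",
    "ONE_VESSEL_PARENCHYMA",
    "TWO_VESSEL_ARTERIAL_PVS",
    "TWO_VESSEL_VENOUS_PVS",
    "TWO_VESSEL_PARENCHYMA",
    "TWO_VESSEL_PARENCHYMA_BAND",
]

ONE_VESSEL_PVS = ("R1", "R2", "R3", "R4")
ONE_VESSEL_PARENCHYMA = ("R5", "R6", "R7")

TWO_VESSEL_ARTERIAL_PVS = ("R1", "R8", "R15", "R22")
TWO_VESSEL_VENOUS_PVS = ("R4", "R11", "R18", "R25")
TWO_VESSEL_PARENCHYMA = (
    "R2", "R3", "R5", "R6", "R7", "R9", "R10", "R12", "R13", "R14",
    "R16", "R17", "R19", "R20", "R21", "R23", "R24",
)
#: Parenchyma elements lying 50–150 μm from the arterial PVS outer boundary:
#: the two vertical grid columns (perpendicular flow is carried by the
#: horizontal members, parallel by the vertical members) and the middle
#: horizontal members spanning the 50–150 μm band.
TWO_VESSEL_PARENCHYMA_BAND = {
    "parallel": ("R2", "R3", "R9", "R10", "R16", "R17", "R23", "R24"),
    "perpendicular": ("R6", "R13", "R20"),
}

_SEGMENT_PER_SOURCE = 100e-6  # three sources × 100 μm = 300 μm vessel segment
_SHORT = 50e-6
_LONG = 100e-6


def _pvs_element(params: ModelParameters, porous_pvs: bool) -> Callable[[float, bool], ResistanceElement]:
    def make(length: float, half: bool = False) -> ResistanceElement:
        if porous_pvs:
            return porous_annulus_element(params, length, half=half)
        return free_annulus_element(params, length, half=half)
    return make


def build_one_vessel(params: ModelParameters, porous_pvs: bool = False) -> HydraulicNetwork:
    """One-vessel network: 7 resistors, 3 sources, both chain ends grounded."""
    pvs = _pvs_element(params, porous_pvs)
    shell = lambda: radial_shell_element(params)
    resistors = [
        Resistor("R1", "n1", GROUND, pvs(_SHORT)),
        Resistor("R2", "n2", "n1", pvs(_LONG)),
        Resistor("R3", "n2", "n3", pvs(_LONG)),
        Resistor("R4", "n3", GROUND, pvs(_SHORT)),
        Resistor("R5", "n1", GROUND, shell()),
        Resistor("R6", "n2", GROUND, shell()),
        Resistor("R7", "n3", GROUND, shell()),
    ]
    p = params.pulse
    sources = [
        SourceAttachment(
            f"IA{i}", f"n{i}",
            PulsatileSource(
                segment_length=_SEGMENT_PER_SOURCE,
                mean_inner_radius=params.pvs.inner_radius,
                amplitude=p.amplitude,
                frequency=p.frequency,
                geometry_factor=FULL_VESSEL_FACTOR,
            ),
        )
        for i in (1, 2, 3)
    ]
    return HydraulicNetwork(resistors=resistors, sources=sources, name="one_vessel")


def build_two_vessel(params: ModelParameters, porous_pvs: bool = False) -> HydraulicNetwork:
    """Two-vessel network: 25 resistors, arterial + venous sources."""
    pvs = _pvs_element(params, porous_pvs)
    slab = lambda length: darcy_slab_element(params, length)
    resistors = [
        # row 0: top boundary elements
        Resistor("R1", "a1", GROUND, pvs(_SHORT, half=True)),
        Resistor("R2", "x1", GROUND, slab(_SHORT)),
        Resistor("R3", "y1", GROUND, slab(_SHORT)),
        Resistor("R4", "v1", GROUND, pvs(_SHORT, half=True)),
        # row 1: horizontal, artery → vein
        Resistor("R5", "a1", "x1", slab(_SHORT)),
        Resistor("R6", "x1", "y1", slab(_LONG)),
        Resistor("R7", "y1", "v1", slab(_SHORT)),
        # rows 1–2: vertical
        Resistor("R8", "a2", "a1", pvs(_LONG, half=True)),
        Resistor("R9", "x1", "x2", slab(_LONG)),
        Resistor("R10", "y1", "y2", slab(_LONG)),
        Resistor("R11", "v2", "v1", pvs(_LONG, half=True)),
        # row 2: horizontal
        Resistor("R12", "a2", "x2", slab(_SHORT)),
        Resistor("R13", "x2", "y2", slab(_LONG)),
        Resistor("R14", "y2", "v2", slab(_SHORT)),
        # rows 2–3: vertical
        Resistor("R15", "a2", "a3", pvs(_LONG, half=True)),
        Resistor("R16", "x2", "x3", slab(_LONG)),
        Resistor("R17", "y2", "y3", slab(_LONG)),
        Resistor("R18", "v2", "v3", pvs(_LONG, half=True)),
        # row 3: horizontal
        Resistor("R19", "a3", "x3", slab(_SHORT)),
        Resistor("R20", "x3", "y3", slab(_LONG)),
        Resistor("R21", "y3", "v3", slab(_SHORT)),
        # row 4: bottom boundary
        Resistor("R22", "a3", GROUND, pvs(_SHORT, half=True)),
        Resistor("R23", "x3", GROUND, slab(_SHORT)),
        Resistor("R24", "y3", GROUND, slab(_SHORT)),
        Resistor("R25", "v3", GROUND, pvs(_SHORT, half=True)),
    ]
    p = params.pulse
    b_ven = venous_amplitude(p.amplitude, p.pulsatility_ratio)
    sources = []
    for i in (1, 2, 3):
        sources.append(SourceAttachment(
            f"IA{i}", f"a{i}",
            PulsatileSource(
                segment_length=_SEGMENT_PER_SOURCE,
                mean_inner_radius=params.pvs.inner_radius,
                amplitude=p.amplitude,
                frequency=p.frequency,
                geometry_factor=HALF_VESSEL_FACTOR,
            ),
        ))
    for i in (1, 2, 3):
        sources.append(SourceAttachment(
            f"IV{i}", f"v{i}",
            PulsatileSource(
                segment_length=_SEGMENT_PER_SOURCE,
                mean_inner_radius=params.pvs.inner_radius,
                amplitude=b_ven,
                frequency=p.frequency,
                phase=p.phase_shift,
                geometry_factor=HALF_VESSEL_FACTOR,
            ),
        ))
    return HydraulicNetwork(resistors=resistors, sources=sources, name="two_vessel")


def build_network(params: ModelParameters, porous_pvs: bool = False) -> HydraulicNetwork:
    """Dispatch on ``params.variant``."""
    if params.variant == "two_vessel":
        return build_two_vessel(params, porous_pvs=porous_pvs)
    return build_one_vessel(params, porous_pvs=porous_pvs)


def describe(network: HydraulicNetwork) -> dict:
    """Human-readable topology description (serializable to YAML/JSON).

    Alternative reconstructions of the figure wiring can be compared
    against this record without reading code.
    """
    return {
        "model": network.name,
        "grounded": sorted(network.grounded),
        "nodes": network.node_ids,
        "resistors": [
            {
                "label": r.label,
                "from": r.node_a,
                "to": r.node_b,
                "kind": r.element.kind,
                "length_m": None if r.element.length != r.element.length else r.element.length,
                "half_annulus": r.element.half_annulus,
                "resistance_Pa_s_per_m3": r.element.resistance,
                "velocity_area_m2": r.element.area,
            }
            for r in network.resistors
        ],
        "sources": [
            {
                "label": s.label,
                "node": s.node,
                "segment_length_m": s.source.segment_length,
                "amplitude_m": s.source.amplitude,
                "frequency_Hz": s.source.frequency,
                "phase_rad": s.source.phase,
                "geometry_factor": s.source.geometry_factor,
            }
            for s in network.sources
        ],
    }
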