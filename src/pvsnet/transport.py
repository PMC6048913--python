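"""Transport-regime diagnostics: Peclet numbers and wavelength checks.

The Peclet number compares convective to diffusive solute transport over a
characteristic length L: Pe = Lv/D.  Three conventions are used here:

* PVS: Pe = L_PVS·v/D*, with L_PVS the full vessel segment length and v the
  peak cross-section-averaged axial velocity.
* Parenchyma, inter-vessel scale: Pe = L_PCY·v/(ϕD*), with L_PCY the
  arteriole–vein distance and v the superficial (Darcy) velocity, whence
  the porosity ϕ in the denominator (v/ϕ is the pore velocity).
* Parenchyma, pore scale: Pe = η·v/(ϕD*), with η the extracellular pore
  size — the customary porous-media convention, applied to the smallest
  diffusivities where the inter-vessel convention would be misleadingly
  pessimistic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .params import ModelParameters

__all__ = ["peclet_pvs", "peclet_parenchyma", "wavelength", "regime_table"]


def peclet_pvs(velocity: float, diffusivity: float, segment_length: float) -> float:
    """Pe = L_PVS·v/D* for axial transport along the perivascular annulus."""
    if diffusivity <= 0 or segment_length <= 0:
        raise ValueError("require D* > 0 and L_PVS > 0")
    return segment_length * velocity / diffusivity


def peclet_parenchyma(velocity: float, diffusivity: float, porosity: float,
                      characteristic_length: float) -> float:
    """Pe = L·v/(ϕD*) with L the inter-vessel distance or the pore size."""
    if diffusivity <= 0 or characteristic_length <= 0:
        raise ValueError("require D* > 0 and L > 0")
    if not 0 < porosity <= 1:
        raise ValueError("require 0 < ϕ ≤ 1")
    return characteristic_length * velocity / (porosity * diffusivity)


def wavelength(wave_speed: float, frequency: float,
               segment_length: float | None = None) -> tuple[float, float | None]:
    """Pulse wavelength c/f and (optionally) its ratio to the segment length.

    A ratio ≫ 1 validates the long-wavelength (lubrication) assumption of
    spatially uniform wall motion along the modeled segment.
    """
    if wave_speed <= 0 or frequency <= 0:
        raise ValueError("require c > 0 and f > 0")
    lam = wave_speed / frequency
    ratio = None if segment_length is None else lam / segment_length
    return lam, ratio


def regime_table(params: ModelParameters, pvs_velocity: float,
                 parenchyma_velocity: float,
                 diffusivities: Sequence[float] = (1e-11, 1e-10, 1e-9),
                 ) -> pd.DataFrame:
    """Peclet numbers across a solute-diffusivity grid (tidy table).

    ``diffusivities`` are in m²/s (defaults span 10–10³ μm²/s).  The pore-size
    length convention is applied to the smallest diffusivity in the grid, the
    inter-vessel convention to the rest.
    """
    d_min = min(diffusivities)
    rows = []
    for D in diffusivities:
        rows.append({
            "model": params.variant,
            "D_star_m2_per_s": D,
            "region": "pvs",
            "length_mode": "segment",
            "Pe": peclet_pvs(pvs_velocity, D, params.pvs.segment_length),
        })
        pore = D == d_min
        length = params.parenchyma.pore_size if pore else params.parenchyma.vessel_separation
        rows.append({
            "model": params.variant,
            "D_star_m2_per_s": D,
            "region": "parenchyma",
            "length_mode": "pore" if pore else "inter_vessel",
            "Pe": peclet_parenchyma(parenchyma_velocity, D,
                                    params.parenchyma.porosity, length),
        })
    return pd.DataFrame(rows)
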