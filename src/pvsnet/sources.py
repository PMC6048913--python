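"""Pulsatile volumetric fluid sources from vessel-wall motion.

The vessel wall (the PVS inner boundary) moves sinusoidally and uniformly
along the modeled segment,

    r_i(t) = R_i − b·cos(2πft − θ),

so the volume enclosed by the wall, V = π l r_i², changes at the rate

    q(t) = dV/dt = 2π l r_i(t) ṙ_i(t)
         = 4π² l f b (R_i sin(2πft − θ) − b sin(2πft − θ) cos(2πft − θ)).

The second term is smaller than the first by b/R_i (≈ 2.5% at baseline),
so the network is driven by the linearized source

    q(t) ≈ g·l·f·b·R_i·sin(2πft − θ),

with geometry factor g = 4π² when the full annulus is modeled (one-vessel
model) and g = 2π² when only the half annulus facing the modeled tissue
slab is resolved (two-vessel model: half of the radially symmetric
displacement enters the modeled region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "FULL_VESSEL_FACTOR",
    "HALF_VESSEL_FACTOR",
    "PulsatileSource",
    "pulsatility",
    "venous_amplitude",
]

FULL_VESSEL_FACTOR = 4.0 * math.pi**2
HALF_VESSEL_FACTOR = 2.0 * math.pi**2


@dataclass(frozen=True)
class PulsatileSource:
    """Sinusoidal volumetric source attached to one network node."""

    segment_length: float  # l, m of vessel modeled by this source
    mean_inner_radius: float  # R_i, m
    amplitude: float  # b, m
    frequency: float  # f, Hz
    phase: float = 0.0  # θ, rad
    geometry_factor: float = FULL_VESSEL_FACTOR  # 4π² or 2π²
    mode: str = "linearized"  # or "exact"

    def __post_init__(self):
        if self.amplitude < 0 or self.amplitude >= self.mean_inner_radius:
            raise ValueError("require 0 ≤ b < R_i")
        if self.frequency <= 0 or self.segment_length <= 0:
            raise ValueError("require f > 0 and l > 0")
        if not math.isclose(self.geometry_factor, FULL_VESSEL_FACTOR) and \
           not math.isclose(self.geometry_factor, HALF_VESSEL_FACTOR):
            raise ValueError("geometry factor must be 4π² (full) or 2π² (half)")
        if self.mode not in ("linearized", "exact"):
            raise ValueError(f"unknown waveform mode {self.mode!r}")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def peak_rate(self) -> float:
        """Amplitude of the linearized source, g·l·f·b·R_i (m³/s)."""
        return (self.geometry_factor * self.segment_length * self.frequency
                * self.amplitude * self.mean_inner_radius)

    def inner_radius(self, t):
        """Instantaneous PVS inner radius r_i(t) = R_i − b·cos(2πft − θ)."""
        t = np.asarray(t, dtype=float)
        return self.mean_inner_radius - self.amplitude * np.cos(
            2.0 * math.pi * self.frequency * t - self.phase
        )

    def rate(self, t):
        """Volumetric flow rate q(t) in m³/s (mode-dependent waveform)."""
        t = np.asarray(t, dtype=float)
        w = 2.0 * math.pi * self.frequency
        if self.mode == "linearized":
            return self.peak_rate * np.sin(w * t - self.phase)
        # exact: dV/dt of the enclosed volume, scaled by the modeled fraction
        # of the annulus (geometry factor relative to the full 4π²).
        fraction = self.geometry_factor / FULL_VESSEL_FACTOR
        r_i = self.inner_radius(t)
        dri_dt = self.amplitude * w * np.sin(w * t - self.phase)
        return fraction * 2.0 * math.pi * self.segment_length * r_i * dri_dt

    def with_(self, **changes) -> "PulsatileSource":
        return replace(self, **changes)


def pulsatility(amplitude: float, frequency: float, interval: float | None = None,
                phase: float = 0.0) -> float:
    """Π = 2∫₀ᵀ |r_i(t) − R_i| dt, by adaptive quadrature (m·s).

    ``interval`` defaults to one pulse period.  Π is strictly linear in the
    amplitude b at fixed f and T, which is all that the venous:arterial
    pulsatility ratio ξ relies on.
    """
    if frequency <= 0:
        raise ValueError("require f > 0")
    T = 1.0 / frequency if interval is None else interval
    if T <= 0:
        raise ValueError("require T > 0")
    if amplitude == 0:
        return 0.0
    w = 2.0 * math.pi * frequency
    # |cos| has kinks at its zeros; hand them to the adaptive quadrature
    k0 = math.ceil((w * 0.0 - phase - math.pi / 2.0) / math.pi)
    kinks = []
    k = k0
    while True:
        t_k = (phase + math.pi / 2.0 + k * math.pi) / w
        if t_k >= T:
            break
        if t_k > 0.0:
            kinks.append(t_k)
        k += 1
    value, _err = quad(
        lambda t: abs(amplitude * math.cos(w * t - phase)), 0.0, T,
        limit=200, points=kinks or None,
    )
    return 2.0 * value


def venous_amplitude(arterial_amplitude: float, pulsatility_ratio: float) -> float:
    """Venous pulse amplitude from the pulsatility ratio ξ.

    Π is proportional to b at shared frequency, so the pulsatility ratio
    reduces to the amplitude ratio: b_ven = ξ·b_art.
    """
    if not 0 <= pulsatility_ratio <= 1:
        raise ValueError("require 0 ≤ ξ ≤ 1")
    return pulsatility_ratio * arterial_amplitude
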