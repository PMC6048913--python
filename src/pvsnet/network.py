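"""Assembly and solution of the linear hydraulic network.

Flow through every resistor obeys the hydraulic Ohm's law Δp = Rq.  With
resistances held constant over the pulse cycle (the quasi-steady,
small-Womersley regime) the network is linear and each time sample is an
independent nodal-analysis solve:

    G p(t) = s(t)

where G is the reduced conductance matrix over the non-grounded nodes
(grounded nodes sit at the zero far-field reference pressure), and s(t)
collects the pulsatile volumetric sources.  G is symmetric positive
definite whenever every node has a resistive path to ground, so a single
Cholesky factorization serves all time samples.

Sign convention: positive flow through a resistor runs from its first to
its second endpoint; the model builders orient resistors away from the
vessel midpoint (axially) and away from the vessel (radially).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .resistances import ResistanceElement
from .sources import PulsatileSource

__all__ = ["GROUND", "Node", "Resistor", "SourceAttachment", "HydraulicNetwork",
           "NetworkSolution", "NetworkError"]

#: Label of the shared zero-pressure reference (far-field CSF/ISF boundary).
GROUND = "GND"


class NetworkError(ValueError):
    """Raised for ill-posed networks (floating nodes, missing endpoints)."""


@dataclass(frozen=True)
class Node:
    id: str
    grounded: bool = False


@dataclass(frozen=True)
class Resistor:
    """Directed network edge; positive flow runs node_a → node_b."""

    label: str
    node_a: str
    node_b: str
    element: ResistanceElement

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise NetworkError(f"resistor {self.label}: endpoints must be distinct")


@dataclass(frozen=True)
class SourceAttachment:
    label: str
    node: str
    source: PulsatileSource


@dataclass
class HydraulicNetwork:
    """A labeled resistor/source graph with grounded boundary nodes."""

    resistors: list[Resistor] = field(default_factory=list)
    sources: list[SourceAttachment] = field(default_factory=list)
    grounded: set[str] = field(default_factory=lambda: {GROUND})
    name: str = "network"

    @property
    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.resistors:
            seen.setdefault(r.node_a)
            seen.setdefault(r.node_b)
        return list(seen)

    @property
    def free_nodes(self) -> list[str]:
        return [n for n in self.node_ids if n not in self.grounded]

    def resistor(self, label: str) -> Resistor:
        for r in self.resistors:
            if r.label == label:
                return r
        raise KeyError(label)

    def validate(self) -> None:
        nodes = set(self.node_ids)
        for s in self.sources:
            if s.node not in nodes:
                raise NetworkError(f"source {s.label} attached to unknown node {s.node}")
        if not (self.grounded & nodes):
            raise NetworkError("no grounded node present")
        floating = self._floating_nodes()
        if floating:
            raise NetworkError(
                "nodes not connected to ground: " + ", ".join(sorted(floating))
            )

    def _floating_nodes(self) -> set[str]:
        adj: dict[str, set[str]] = {}
        for r in self.resistors:
            adj.setdefault(r.node_a, set()).add(r.node_b)
            adj.setdefault(r.node_b, set()).add(r.node_a)
        reached = set(g for g in self.grounded if g in adj)
        stack = list(reached)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in reached:
                    reached.add(nb)
                    stack.append(nb)
        return set(adj) - reached

    # -- assembly & solve ------------------------------------------------

    def assemble(self) -> tuple[np.ndarray, list[str]]:
        """Reduced conductance matrix over free nodes and their ordering."""
        self.validate()
        free = self.free_nodes
        index = {n: i for i, n in enumerate(free)}
        G = np.zeros((len(free), len(free)))
        for r in self.resistors:
            g = 1.0 / r.element.resistance
            ia = index.get(r.node_a)
            ib = index.get(r.node_b)
            if ia is not None:
                G[ia, ia] += g
            if ib is not None:
                G[ib, ib] += g
            if ia is not None and ib is not None:
                G[ia, ib] -= g
                G[ib, ia] -= g
        return G, free

    def period(self) -> float:
        if not self.sources:
            raise NetworkError("network has no sources; period undefined")
        return max(s.source.period for s in self.sources)

    def solve_period(self, n_samples: int = 256) -> "NetworkSolution":
        """Solve nodal pressures and resistor flows over one pulse period.

        The time grid spans exactly [0, T] inclusive, so trapezoidal
        integrals over the full period vanish identically for sinusoidal
        sources.
        """
        if n_samples < 16:
            raise ValueError("n_samples must be ≥ 16")
        G, free = self.assemble()
        T = self.period()
        times = np.linspace(0.0, T, n_samples + 1)

        S = np.zeros((len(free), times.size))
        index = {n: i for i, n in enumerate(free)}
        for s in self.sources:
            if s.node in index:
                S[index[s.node]] += s.source.rate(times)

        try:
            factor = cho_factor(G)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate
            raise NetworkError(f"singular conductance matrix: {exc}") from exc
        P = cho_solve(factor, S)  # (n_free, n_t)

        flows = np.empty((len(self.resistors), times.size))
        for k, r in enumerate(self.resistors):
            pa = P[index[r.node_a]] if r.node_a in index else 0.0
            pb = P[index[r.node_b]] if r.node_b in index else 0.0
            flows[k] = (pa - pb) / r.element.resistance

        return NetworkSolution(network=self, times=times,
                               node_order=free, pressures=P, flows=flows)


@dataclass
class NetworkSolution:
    """Pressures and flows over one period plus derived peak metrics."""

    network: HydraulicNetwork
    times: np.ndarray  # (n_t,), inclusive of both period endpoints
    node_order: list[str]
    pressures: np.ndarray  # (n_free, n_t), Pa relative to ground
    flows: np.ndarray  # (n_resistors, n_t), m³/s

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def _res_index(self, label: str) -> int:
        for k, r in enumerate(self.network.resistors):
            if r.label == label:
                return k
        raise KeyError(label)

    # -- accessors -------------------------------------------------------

    def pressure(self, node: str) -> np.ndarray:
        if node in self.network.grounded:
            return np.zeros_like(self.times)
        return self.pressures[self.node_order.index(node)]

    def flow(self, label: str) -> np.ndarray:
        return self.flows[self._res_index(label)]

    def velocity(self, label: str, radius: Optional[float] = None) -> np.ndarray:
        """Superficial fluid velocity q/A (m/s), optionally at a shell radius."""
        r = self.network.resistor(label)
        return self.flow(label) / r.element.velocity_area(radius)

    # -- peak metrics ----------------------------------------------------

    def peak_pressure(self) -> float:
        """max over time and free nodes of |p| (Pa)."""
        return float(np.abs(self.pressures).max()) if self.pressures.size else 0.0

    def peak_velocity(self, labels: Optional[Iterable[str]] = None,
                      radius: Optional[float] = None) -> float:
        """max over time and the given resistors of |q|/A (m/s)."""
        labels = [r.label for r in self.network.resistors] if labels is None else list(labels)
        return max(float(np.abs(self.velocity(l, radius)).max()) for l in labels)

    def peak_flow(self, label: str) -> float:
        return float(np.abs(self.flow(label)).max())

    def velocity_at(self, label: str, t: float, radius: Optional[float] = None) -> float:
        """Signed velocity at time ``t`` (nearest sample)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.velocity(label, radius)[i])

    def net_volume(self, label: str) -> float:
        """Trapezoidal ∫q dt over the full period (m³); ≈ 0 for pure oscillation."""
        return float(np.trapezoid(self.flow(label), self.times))

    def kirchhoff_residual(self) -> float:
        """Max over samples/nodes of |Σq_in − s| relative to the peak source."""
        index = {n: i for i, n in enumerate(self.node_order)}
        resid = np.zeros((len(self.node_order), self.times.size))
        for k, r in enumerate(self.network.resistors):
            if r.node_a in index:
                resid[index[r.node_a]] += self.flows[k]
            if r.node_b in index:
                resid[index[r.node_b]] -= self.flows[k]
        for s in self.network.sources:
            if s.node in index:
                resid[index[s.node]] -= s.source.rate(self.times)
        scale = max(
            (abs(s.source.peak_rate) for s in self.network.sources), default=0.0
        )
        if scale == 0.0:
            return float(np.abs(resid).max())
        return float(np.abs(resid).max() / scale)

    # -- tabular export --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy time series: t, p per node, q and v per resistor."""
        data: dict[str, np.ndarray] = {"t": self.times}
        for n in self.node_order:
            data[f"p[{n}]"] = self.pressure(n)
        for r in self.network.resistors:
            data[f"q[{r.label}]"] = self.flow(r.label)
            data[f"v[{r.label}]"] = self.velocity(r.label)
        return pd.DataFrame(data)

    def summary(self) -> dict:
        """Peak metrics and net volumes keyed by node / resistor label."""
        return {
            "model": self.network.name,
            "period_s": self.period,
            "n_samples": int(self.times.size - 1),
            "peak_pressure_Pa": self.peak_pressure(),
            "peak_pressure_per_node_Pa": {
                n: float(np.abs(self.pressure(n)).max()) for n in self.node_order
            },
            "peak_velocity_per_resistor_m_per_s": {
                r.label: float(np.abs(self.velocity(r.label)).max())
                for r in self.network.resistors
            },
            "net_volume_per_resistor_m3": {
                r.label: self.net_volume(r.label) for r in self.network.resistors
            },
            "kirchhoff_residual_rel": self.kirchhoff_residual(),
        }
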