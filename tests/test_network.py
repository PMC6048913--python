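"""Nodal assembly and period solves on small hand-checkable networks."""

import math

import numpy as np
import pytest

from pvsnet import (
    GROUND,
    HydraulicNetwork,
    ModelParameters,
    NetworkError,
    PulsatileSource,
    Resistor,
    SourceAttachment,
    build_one_vessel,
)
from pvsnet.resistances import ResistanceElement


def element(R, area=1e-9):
    return ResistanceElement(kind="darcy_slab", resistance=R, area=area, length=1e-6)


def source(node, label="S1", amplitude=0.1e-6, phase=0.0):
    return SourceAttachment(label, node, PulsatileSource(
        segment_length=100e-6, mean_inner_radius=10e-6,
        amplitude=amplitude, frequency=5.0, phase=phase))


class TestAssembly:
    def test_single_resistor_gives_1x1_reciprocal(self):
        net = HydraulicNetwork(resistors=[Resistor("R1", "n1", GROUND, element(2e12))],
                               sources=[source("n1")])
        G, free = net.assemble()
        assert free == ["n1"]
        assert G[0, 0] == pytest.approx(0.5e-12)

    def test_two_series_resistors_match_hand_elimination(self):
        R = 1e12
        net = HydraulicNetwork(
            resistors=[Resistor("R1", "n1", "n2", element(R)),
                       Resistor("R2", "n2", GROUND, element(R))],
            sources=[source("n1")])
        sol = net.solve_period(64)
        q = source("n1").source.peak_rate
        # all source flow passes through both resistors: p1 = 2Rq, p2 = Rq
        assert np.abs(sol.pressure("n1")).max() == pytest.approx(2 * R * q, rel=1e-12)
        assert np.abs(sol.pressure("n2")).max() == pytest.approx(R * q, rel=1e-12)

    def test_floating_node_raises_naming_it(self):
        net = HydraulicNetwork(
            resistors=[Resistor("R1", "n1", GROUND, element(1e12)),
                       Resistor("R2", "lost1", "lost2", element(1e12))],
            sources=[source("n1")])
        with pytest.raises(NetworkError, match="lost1"):
            net.assemble()

    def test_source_on_unknown_node_rejected(self):
        net = HydraulicNetwork(resistors=[Resistor("R1", "n1", GROUND, element(1e12))],
                               sources=[source("nowhere")])
        with pytest.raises(NetworkError, match="nowhere"):
            net.validate()

    def test_one_vessel_system_matches_symmetric_chain_oracle(self, baseline):
        """Closed-form nodal analysis of the symmetric 3-node chain.

        With end conductance g1, mid conductance g2, radial shunt gr and
        equal in-phase sources A at each node, symmetry (p1 = p3) reduces
        the system to 2×2, solved here by Cramer's rule.
        """
        net = build_one_vessel(baseline)
        g1 = 1 / net.resistor("R1").element.resistance
        g2 = 1 / net.resistor("R2").element.resistance
        gr = 1 / net.resistor("R5").element.resistance
        A = net.sources[0].source.peak_rate
        a11, a12 = g1 + g2 + gr, -g2
        a21, a22 = -2 * g2, 2 * g2 + gr
        det = a11 * a22 - a12 * a21
        p1 = (A * a22 - A * a12) / det
        p2 = (a11 * A - a21 * A) / det
        sol = net.solve_period(64)
        assert np.abs(sol.pressure("n1")).max() == pytest.approx(p1, rel=1e-10)
        assert np.abs(sol.pressure("n2")).max() == pytest.approx(p2, rel=1e-10)


class TestSolvePeriod:
    def test_silent_sources_mean_rest(self, baseline):
        net = build_one_vessel(baseline.evolve(b=0.0))
        sol = net.solve_period(64)
        assert np.all(sol.pressures == 0.0)
        assert np.all(sol.flows == 0.0)

    def test_peaks_linear_in_amplitude(self, baseline):
        sol1 = build_one_vessel(baseline).solve_period(64)
        sol2 = build_one_vessel(baseline.evolve(b=0.5e-6)).solve_period(64)
        assert sol2.peak_pressure() == pytest.approx(2 * sol1.peak_pressure(), rel=1e-12)
        for label in ("R1", "R2", "R6"):
            assert sol2.peak_flow(label) == pytest.approx(2 * sol1.peak_flow(label), rel=1e-12)

    def test_superposition_of_sources(self):
        """Solution for sources A+B equals the sum of separate solutions."""
        resistors = [Resistor("R1", "n1", GROUND, element(1e12)),
                     Resistor("R2", "n1", "n2", element(3e12)),
                     Resistor("R3", "n2", GROUND, element(2e12))]
        sa, sb = source("n1", "SA"), source("n2", "SB", amplitude=0.07e-6, phase=0.9)
        both = HydraulicNetwork(resistors=resistors, sources=[sa, sb]).solve_period(64)
        only_a = HydraulicNetwork(resistors=resistors, sources=[sa]).solve_period(64)
        only_b = HydraulicNetwork(resistors=resistors, sources=[sb]).solve_period(64)
        np.testing.assert_allclose(both.pressures, only_a.pressures + only_b.pressures,
                                   rtol=1e-10, atol=1e-18)

    def test_mass_conserved_at_every_node(self, one_vessel_solution, two_vessel_solution):
        assert one_vessel_solution.kirchhoff_residual() < 1e-10
        assert two_vessel_solution.kirchhoff_residual() < 1e-10

    def test_minimum_sampling_enforced(self, baseline):
        with pytest.raises(ValueError):
            build_one_vessel(baseline).solve_period(8)

    def test_peaks_insensitive_to_doubling_the_sampling(self, baseline,
                                                        one_vessel_solution):
        fine = build_one_vessel(baseline).solve_period(512)
        coarse = one_vessel_solution  # 256 samples
        assert fine.peak_pressure() == pytest.approx(coarse.peak_pressure(), rel=1e-3)
        for label in ("R1", "R6"):
            assert fine.peak_flow(label) == pytest.approx(coarse.peak_flow(label),
                                                          rel=1e-3)


class TestVelocityConversion:
    def test_velocity_is_flow_over_area(self, one_vessel_solution):
        sol = one_vessel_solution
        r = sol.network.resistor("R1")
        np.testing.assert_allclose(sol.velocity("R1"),
                                   sol.flow("R1") / r.element.area, rtol=1e-14)

    def test_shell_velocity_falls_with_radius(self, one_vessel_solution):
        near = np.abs(one_vessel_solution.velocity("R6", radius=30e-6)).max()
        far = np.abs(one_vessel_solution.velocity("R6", radius=80e-6)).max()
        assert far == pytest.approx(near * 30 / 80, rel=1e-12)

    def test_radius_outside_shell_rejected(self, one_vessel_solution):
        with pytest.raises(ValueError):
            one_vessel_solution.velocity("R6", radius=1e-3)


class TestNetFlow:
    def test_oscillation_has_no_net_volume(self, one_vessel_solution):
        sol = one_vessel_solution
        for r in sol.network.resistors:
            bound = 1e-9 * sol.peak_flow(r.label) * sol.period
            assert abs(sol.net_volume(r.label)) < bound

    def test_half_period_integral_is_nonzero(self, baseline):
        """The integrator detects the oscillation it cancels over a full period."""
        sol = build_one_vessel(baseline).solve_period(128)
        half = sol.times <= sol.period / 2 + 1e-12
        half_vol = np.trapezoid(sol.flow("R1")[half], sol.times[half])
        assert abs(half_vol) > 0.1 * sol.peak_flow("R1") * sol.period

    def test_integrator_sanity_on_constant_flow(self, one_vessel_solution):
        # trapezoid of a constant equals value × period
        sol = one_vessel_solution
        const = np.full_like(sol.times, 3.3e-14)
        assert np.trapezoid(const, sol.times) == pytest.approx(3.3e-14 * sol.period, rel=1e-12)


class TestExports:
    def test_frame_has_all_columns(self, one_vessel_solution):
        frame = one_vessel_solution.to_frame()
        assert "t" in frame.columns
        for n in ("n1", "n2", "n3"):
            assert f"p[{n}]" in frame.columns
        for r in ("R1", "R7"):
            assert f"q[{r}]" in frame.columns and f"v[{r}]" in frame.columns

    def test_summary_metrics_consistent(self, one_vessel_solution):
        s = one_vessel_solution.summary()
        assert s["peak_pressure_Pa"] == pytest.approx(
            max(s["peak_pressure_per_node_Pa"].values()))
        assert s["kirchhoff_residual_rel"] < 1e-10
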