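"""Resistance formulas against independent numerical oracles.

The annulus formula is checked against quadrature of the analytic annular
Poiseuille velocity profile (flow for unit pressure drop), and the radial
shell formula against a one-dimensional finite-difference Darcy solve.
Neither oracle shares code with the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pvsnet import (
    ModelParameters,
    annular_area,
    annular_poiseuille_resistance,
    darcy_slab_resistance,
    porous_annulus_resistance,
    radial_shell_resistance,
    womersley_number,
)
from pvsnet.resistances import (
    darcy_slab_element,
    free_annulus_element,
    porous_annulus_element,
    radial_shell_element,
)

MU = 0.9e-3
BASE = dict(mu=MU, length=100e-6, outer_radius=30e-6, radius_ratio=1 / 3)


def annulus_resistance_by_quadrature(mu, length, r_outer, ratio):
    """R = Δp/q from the analytic velocity profile, integrated numerically.

    For axial flow with constant pressure gradient G, the profile is
    u(r) = (G/4μ)[R_o² − r² + (R_o² − R_i²)·ln(r/R_o)/ln(R_o/R_i)].
    """
    r_inner = ratio * r_outer
    c = (r_outer**2 - r_inner**2) / math.log(r_outer / r_inner)

    def integrand(r):
        u = (r_outer**2 - r**2 + c * math.log(r / r_outer)) / (4 * mu)
        return 2 * math.pi * r * u

    q_per_gradient, _ = quad(integrand, r_inner, r_outer, limit=200)
    return length / q_per_gradient  # Δp = G·l ⇒ R = l/(q/G)


def shell_resistance_by_finite_difference(K, h, r_in, r_out, n=10_000):
    """Series sum of thin-shell Darcy resistances Δr/(2π r_mid h K)."""
    edges = np.linspace(r_in, r_out, n + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    return float(np.sum(np.diff(edges) / (2 * math.pi * mid * h * K)))


class TestAnnularPoiseuille:
    def test_baseline_matches_quadrature_oracle(self):
        R = annular_poiseuille_resistance(**BASE)
        oracle = annulus_resistance_by_quadrature(MU, 100e-6, 30e-6, 1 / 3)
        assert R == pytest.approx(oracle, rel=1e-10)
        assert R == pytest.approx(1.05e12, rel=0.01)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(ratio=st.floats(0.05, 0.97), r_outer=st.floats(2e-6, 100e-6))
    def test_agrees_with_oracle_across_geometries(self, ratio, r_outer):
        R = annular_poiseuille_resistance(MU, 100e-6, r_outer, ratio)
        oracle = annulus_resistance_by_quadrature(MU, 100e-6, r_outer, ratio)
        assert R == pytest.approx(oracle, rel=1e-8)

    def test_narrow_ratio_approaches_open_pipe(self):
        # E → 0: (E² − 1)²/ln E → 0 (only logarithmically fast), leaving
        # the Hagen–Poiseuille pipe value
        pipe = 8 * MU * 100e-6 / (math.pi * (30e-6) ** 4)
        devs = [abs(annular_poiseuille_resistance(MU, 100e-6, 30e-6, E) / pipe - 1)
                for E in (1e-3, 1e-9, 1e-30)]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.02

    def test_linear_in_length(self):
        one = annular_poiseuille_resistance(**BASE)
        two = annular_poiseuille_resistance(**{**BASE, "length": 200e-6})
        assert two == pytest.approx(2 * one, rel=1e-14)

    @pytest.mark.parametrize("ratio", [0.0, 1.0, 1.5, -0.1])
    def test_ratio_domain_errors(self, ratio):
        with pytest.raises(ValueError):
            annular_poiseuille_resistance(MU, 100e-6, 30e-6, ratio)


class TestRadialShell:
    def test_baseline_matches_finite_difference_oracle(self):
        R = radial_shell_resistance(5.63e-12, 100e-6, 10e-6, 300e-6)
        oracle = shell_resistance_by_finite_difference(5.63e-12, 100e-6, 10e-6, 300e-6)
        assert R == pytest.approx(oracle, rel=1e-6)
        assert R == pytest.approx(9.6e14, rel=0.01)

    def test_equal_radii_means_zero_resistance(self):
        assert radial_shell_resistance(5.63e-12, 100e-6, 50e-6, 50e-6) == 0.0

    def test_inverse_in_conductivity(self):
        lo = radial_shell_resistance(5.63e-12, 100e-6, 10e-6, 300e-6)
        hi = radial_shell_resistance(2 * 5.63e-12, 100e-6, 10e-6, 300e-6)
        assert hi == pytest.approx(lo / 2, rel=1e-14)

    def test_radii_out_of_order_rejected(self):
        with pytest.raises(ValueError):
            radial_shell_resistance(5.63e-12, 100e-6, 300e-6, 10e-6)


class TestPorousAnnulus:
    def test_conductivity_matching_free_fluid_value(self):
        """K chosen to equal the free-fluid resistance reproduces it exactly."""
        R_free = annular_poiseuille_resistance(**BASE)
        K_eq = 100e-6 / (math.pi * ((30e-6) ** 2 - (10e-6) ** 2) * R_free)
        R_porous = porous_annulus_resistance(K_eq, 100e-6, 10e-6, 30e-6)
        assert R_porous == pytest.approx(R_free, rel=1e-12)

    def test_limits(self):
        # K → ∞ ⇒ R → 0 (vanishing relative to the physiological scale)
        base = porous_annulus_resistance(5.63e-12, 100e-6, 10e-6, 30e-6)
        assert porous_annulus_resistance(1e6, 100e-6, 10e-6, 30e-6) < 1e-12 * base
        assert porous_annulus_resistance(5.63e-12, 0.0, 10e-6, 30e-6) == 0.0

    def test_degenerate_annulus_rejected(self):
        with pytest.raises(ValueError):
            porous_annulus_resistance(5.63e-12, 100e-6, 30e-6, 30e-6)


class TestDarcySlab:
    def test_against_darcy_law(self):
        # q = K·A·Δp/l with unit Δp ⇒ R = l/(K·A)
        R = darcy_slab_resistance(5.63e-12, 100e-6, 100e-6, 200e-6)
        assert R == pytest.approx(100e-6 / (5.63e-12 * 100e-6 * 200e-6), rel=1e-14)
        assert R == pytest.approx(8.88e14, rel=0.01)

    def test_area_scaling(self):
        one = darcy_slab_resistance(5.63e-12, 100e-6, 100e-6, 200e-6)
        wide = darcy_slab_resistance(5.63e-12, 100e-6, 100e-6, 400e-6)
        assert wide == pytest.approx(one / 2, rel=1e-14)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            darcy_slab_resistance(5.63e-12, 100e-6, -1e-6, 200e-6)


class TestWomersley:
    def test_baseline_is_small(self):
        alpha = womersley_number(10e-6, 30e-6, 5.0, 993.2, 0.9e-3)
        assert alpha == pytest.approx(
            2 * 20e-6 * math.sqrt(2 * math.pi * 5 * 993.2 / 0.9e-3), rel=1e-12
        )
        assert alpha == pytest.approx(0.24, abs=0.01)
        assert alpha < 1  # quasi-steady regime

    def test_static_limit_and_frequency_scaling(self):
        assert womersley_number(10e-6, 30e-6, 0.0, 993.2, 0.9e-3) == 0.0
        a1 = womersley_number(10e-6, 30e-6, 5.0, 993.2, 0.9e-3)
        a4 = womersley_number(10e-6, 30e-6, 20.0, 993.2, 0.9e-3)
        assert a4 == pytest.approx(2 * a1, rel=1e-12)


class TestElements:
    def test_half_annulus_doubles_resistance(self, baseline):
        full = free_annulus_element(baseline, 100e-6)
        half = free_annulus_element(baseline, 100e-6, half=True)
        assert half.resistance == pytest.approx(2 * full.resistance, rel=1e-15)
        # velocity conversion uses the full annular cross-section (see
        # methods note): the reported velocity is that of the whole PVS
        assert half.area == pytest.approx(annular_area(10e-6, 30e-6), rel=1e-15)
        porous_half = porous_annulus_element(baseline, 100e-6, half=True)
        porous_full = porous_annulus_element(baseline, 100e-6)
        assert porous_half.resistance == pytest.approx(2 * porous_full.resistance)

    def test_shell_velocity_area_varies_with_radius(self, baseline):
        el = radial_shell_element(baseline)
        assert el.velocity_area() == pytest.approx(2 * math.pi * 30e-6 * 100e-6)
        assert el.velocity_area(80e-6) == pytest.approx(2 * math.pi * 80e-6 * 100e-6)
        with pytest.raises(ValueError):
            el.velocity_area(400e-6)

    def test_slab_element_area(self, baseline):
        el = darcy_slab_element(baseline, 50e-6)
        assert el.area == pytest.approx(100e-6 * 200e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1.1, 100.0))
    def test_resistance_decreases_with_conductivity(self, baseline, scale):
        base = radial_shell_element(baseline).resistance
        more = radial_shell_element(
            baseline.evolve(K=5.63e-12 * scale)).resistance
        assert more < base
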