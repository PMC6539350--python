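"""Closed-form elastica vs independent beam mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvelastica import elastica as el
from oracles import (
    linear_cantilever_tip_deflection,
    ode_elastica,
    quadrature_incomplete_first,
)


class TestEccentricityAndAmplitude:
    @pytest.mark.parametrize(
        "theta_l, alpha, expected",
        [
            (0.3, 0.3, math.sqrt(2) / 2),                     # equal angles
            (math.pi / 2 - 1e-12, 0.0, 1.0),                  # vertical tip slope
            (math.radians(32.6), math.radians(10.0),
             math.sqrt((1 + math.sin(math.radians(22.6))) / 2)),
        ],
    )
    def test_eccentricity_values(self, theta_l, alpha, expected):
        assert el.eccentricity_from_angles(theta_l, alpha) == pytest.approx(expected, abs=1e-12)

    def test_eccentricity_rejects_degenerate_pairing(self):
        with pytest.raises(el.ElasticaDomainError):
            el.eccentricity_from_angles(-math.pi / 2 + 1e-15, 0.0)

    @pytest.mark.parametrize(
        "k, alpha, expected",
        [
            (math.sqrt(2) / 2, 0.0, math.pi / 2),
            (0.9, math.pi / 2 - 1e-12, 0.0),
            (el.eccentricity_from_angles(math.radians(56.8), math.radians(20)),
             math.radians(20.0), None),  # value checked against its identity below
        ],
    )
    def test_reference_amplitude(self, k, alpha, expected):
        phi = el.reference_amplitude(k, alpha)
        if expected is not None:
            assert phi == pytest.approx(expected, abs=1e-6)
        # defining identity 2 k^2 sin^2 phi = 1 - sin alpha
        assert 2 * k * k * math.sin(phi) ** 2 == pytest.approx(1 - math.sin(alpha), abs=1e-12)

    def test_reference_amplitude_rejects_incompatible_pair(self):
        with pytest.raises(el.ElasticaDomainError):
            el.reference_amplitude(0.3, 0.0)    # (1-0)/(2*0.09) > 1

    def test_load_frequency_zero_for_straight_beam(self):
        k = el.eccentricity_from_angles(0.0, 0.0)
        phi = el.reference_amplitude(k, 0.0)
        assert el.load_frequency(k, phi) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("theta_l, alpha", [(0.7, 0.2), (1.1, 0.0), (0.4, 0.35)])
    def test_load_frequency_matches_quadrature(self, theta_l, alpha):
        k = el.eccentricity_from_angles(theta_l, alpha)
        phi_a = el.reference_amplitude(k, alpha)
        omega = el.load_frequency(k, phi_a)
        oracle = (quadrature_incomplete_first(math.pi / 2, k)
                  - quadrature_incomplete_first(phi_a, k))
        assert omega == pytest.approx(oracle, rel=1e-10)


class TestAmplitudeField:
    def test_amplitude_endpoints_and_monotonicity(self):
        sol = el.solve_elastica(0.8, 0.25, 18.0, 500.0)
        s = np.linspace(0, 1, 41)
        phi = el.amplitude_at(s, sol.omega, sol.phi_alpha, sol.k)
        assert phi[0] == pytest.approx(sol.phi_alpha, abs=1e-12)
        assert phi[-1] == pytest.approx(math.pi / 2, abs=1e-10)
        assert np.all(np.diff(phi) > 0)

    def test_amplitude_inverts_incomplete_integral(self):
        sol = el.solve_elastica(0.9, 0.1, 18.0, 500.0)
        for s in (0.25, 0.5, 0.75):
            phi = float(el.amplitude_at(s, sol.omega, sol.phi_alpha, sol.k))
            # F[phi(s),k] - F[phi_alpha,k] telescopes to omega*s
            lhs = (quadrature_incomplete_first(phi, sol.k)
                   - quadrature_incomplete_first(sol.phi_alpha, sol.k))
            assert lhs == pytest.approx(sol.omega * s, rel=1e-9)


class TestShapeAgainstBeamMechanics:
    def test_root_is_clamped_at_origin(self):
        sol = el.solve_elastica(0.7, 0.3, 18.0, 500.0)
        x0, y0 = el.shape(0.0, sol)
        assert abs(x0) < 1e-12 and abs(y0) < 1e-12

    def test_tip_position_equals_shape_at_one(self):
        sol = el.solve_elastica(0.55, 0.15, 13.0, 500.0)
        x1, y1 = el.shape(1.0, sol)
        assert np.allclose(sol.tip, [x1, y1], atol=1e-12)

    @pytest.mark.parametrize("theta_l, alpha", [(0.7, 0.35), (0.9, 0.1), (0.3, 0.2),
                                                (1.2, 0.5), (0.15, 0.02)])
    def test_shape_matches_ode_integration(self, theta_l, alpha):
        sol = el.solve_elastica(theta_l, alpha, 18.0, 500.0)
        s, x_hat, y_hat, theta, kappa0 = ode_elastica(theta_l, alpha, sol.omega)
        x, y = el.shape(s, sol)
        assert np.max(np.hypot(x / 18.0 - x_hat, y / 18.0 - y_hat)) < 1e-7

    def test_zero_load_gives_straight_horizontal_beam(self):
        sol = el.solve_elastica(0.0, 0.0, 18.0, 500.0)
        assert sol.P == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sol.tip, [18.0, 0.0], atol=1e-8)
        assert sol.root_moment == pytest.approx(0.0, abs=1e-8)

    def test_linear_euler_bernoulli_limit(self):
        # small end slope, vertical load: classic P l^3 / 3B sag
        sol = el.solve_elastica(math.radians(1.5), 0.0, 18.0, 500.0)
        sag = linear_cantilever_tip_deflection(sol.P, 18.0, 500.0)
        assert sol.tip[1] == pytest.approx(sag, rel=0.02)

    def test_doubling_stiffness_doubles_load(self):
        p1 = el.solve_elastica(0.6, 0.2, 18.0, 500.0).P
        p2 = el.solve_elastica(0.6, 0.2, 18.0, 1000.0).P
        assert p2 == pytest.approx(2 * p1, rel=1e-12)


class TestMomentsAndCurvature:
    def test_tip_curvature_vanishes(self):
        sol = el.solve_elastica(1.0, 0.4, 18.0, 500.0)
        assert abs(el.curvature_at(1.0, sol)) * 18.0 < 1e-9

    def test_root_moment_equals_statics_cross_product(self):
        # M(0) = |b x F| with F of magnitude P directed (-sin a, cos a)
        sol = el.solve_elastica(0.8, 0.3, 18.0, 500.0)
        fx, fy = -sol.P * math.sin(0.3), sol.P * math.cos(0.3)
        m_static = abs(sol.tip[0] * fy - sol.tip[1] * fx)
        assert sol.root_moment == pytest.approx(m_static, rel=1e-10)

    def test_curvature_matches_tangent_angle_differences(self):
        sol = el.solve_elastica(0.75, 0.2, 18.0, 500.0)
        s = np.linspace(0.05, 0.95, 19)
        h = 1e-5
        th_p = el.tangent_angle_at(s + h, sol)
        th_m = el.tangent_angle_at(s - h, sol)
        fd = (th_p - th_m) / (2 * h) / 18.0
        assert np.allclose(fd, el.curvature_at(s, sol), rtol=1e-6, atol=1e-10)

    def test_moment_field_balances_tip_force(self):
        # B theta'(s) equals the moment of the tip force about the point s
        sol = el.solve_elastica(0.9, 0.25, 18.0, 500.0)
        s = np.linspace(0.0, 1.0, 21)
        x, y = el.shape(s, sol)
        fx, fy = -sol.P * math.sin(0.25), sol.P * math.cos(0.25)
        lever = (sol.tip[0] - x) * fy - (sol.tip[1] - y) * fx
        moment = 500.0 * el.curvature_at(s, sol)
        assert np.allclose(moment, lever, atol=1e-8 * 500.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(theta_l=st.floats(math.radians(2), math.radians(80)),
       alpha=st.floats(0.0, math.radians(60)))
def test_invariants_random_parameters(theta_l, alpha):
    """Inextensibility, omega-load consistency and tip flatness everywhere."""
    sol = el.solve_elastica(theta_l, alpha, 18.0, 500.0)
    assert sol.P == pytest.approx(500.0 * sol.omega ** 2 / 18.0 ** 2, rel=1e-14)
    s = np.linspace(0, 1, 4001)
    x, y = el.shape(s, sol)
    arc = np.sum(np.hypot(np.diff(x), np.diff(y)))
    assert arc == pytest.approx(18.0, rel=1e-6)
    assert abs(el.curvature_at(1.0, sol)) * 18.0 < 1e-9


def test_params_validation():
    with pytest.raises(ValueError):
        el.ElasticaParams(l=-1.0, B=500.0, theta_l=0.1, alpha=0.0)
    with pytest.raises(ValueError):
        el.ElasticaParams(l=18.0, B=500.0, theta_l=2.0, alpha=0.0)
    with pytest.raises(ValueError):
        el.ElasticaParams(l=18.0, B=500.0, theta_l=0.1, alpha=-0.2)
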