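"""Surgical scenarios: constraint satisfaction, optimisation and indicators."""

import dataclasses
import math

import numpy as np
import pytest

from mvelastica.postop import (
    Scenario,
    indicators,
    optimize_pma,
    postop_residuals,
    solve_scenario,
)
from mvelastica.preop import _build_geometry, finalize_preop, identify_preop
from mvelastica.valve_system import ValveMeasurements


@pytest.fixture(scope="module")
def optimized(reference_preop, reference_case):
    return optimize_pma(reference_preop, reference_case, seed=5, n_draws=60)


def _unknowns_of(postop):
    s = postop.system
    return (s.theta_a, s.theta_p, s.alpha_a, s.alpha_p,
            float(postop.surgical.u_a[0]), float(-postop.surgical.u_p[0]),
            postop.surgical.r)


class TestResidualVector:
    def test_solved_configuration_has_zero_residual(self, optimized,
                                                    reference_preop, reference_case):
        res = postop_residuals(_unknowns_of(optimized), reference_preop,
                               reference_case, optimized.surgical.zeta_a,
                               optimized.surgical.zeta_p)
        assert np.max(np.abs(res)) < 1e-8
        assert optimized.residual_norm < 1e-8

    def test_coaptation_violation_is_local(self, optimized, reference_preop,
                                           reference_case):
        # raising the target height by 1 mm moves exactly the two tip-height
        # components, by 1/MAD each
        res0 = postop_residuals(_unknowns_of(optimized), reference_preop,
                                reference_case, optimized.surgical.zeta_a,
                                optimized.surgical.zeta_p)
        meas2 = reference_case.with_(TH_opt=reference_case.TH_opt + 1.0)
        res1 = postop_residuals(_unknowns_of(optimized), reference_preop, meas2,
                                optimized.surgical.zeta_a, optimized.surgical.zeta_p)
        diff = res1 - res0
        expected = np.zeros(7)
        expected[4] = expected[5] = -1.0 / reference_case.MAD_pre
        assert np.allclose(diff, expected, atol=1e-12)

    def test_infeasible_point_yields_large_finite_residual(self, reference_preop,
                                                           reference_case):
        res = postop_residuals((2.0, 0.5, 0.1, 0.1, 0.0, 0.0, 5.0),
                               reference_preop, reference_case, 0.0, 0.0)
        assert np.all(np.isfinite(res))

    def test_residuals_smooth_in_unknowns(self, optimized, reference_preop,
                                          reference_case):
        """Finite-difference Jacobian is step-size stable (smooth residuals)."""
        z0 = np.array(_unknowns_of(optimized))
        za, zp = optimized.surgical.zeta_a, optimized.surgical.zeta_p

        def jac(h):
            J = np.empty((7, 7))
            for j in range(7):
                dz = np.zeros(7)
                dz[j] = h
                J[:, j] = (postop_residuals(z0 + dz, reference_preop, reference_case, za, zp)
                           - postop_residuals(z0 - dz, reference_preop, reference_case, za, zp)
                           ) / (2 * h)
            return J

        J1, J2 = jac(1e-6), jac(2e-6)
        assert np.allclose(J1, J2, rtol=1e-3, atol=1e-6)


class TestOptimizedScenario:
    def test_constraints_satisfied(self, optimized, reference_case):
        s = optimized.system
        assert s.b_a[1] == pytest.approx(reference_case.TH_opt, abs=1e-9)
        assert s.b_p[1] == pytest.approx(reference_case.TH_opt, abs=1e-9)
        assert np.allclose(s.b_a, s.b_p, atol=1e-9)      # tips coapt
        assert optimized.MAD_po == pytest.approx(
            reference_case.MAD_pre - optimized.surgical.r, rel=1e-12)

    def test_single_draw_equals_solve_scenario(self, reference_preop, reference_case):
        one = optimize_pma(reference_preop, reference_case, seed=9, n_draws=1)
        pair = (one.surgical.zeta_a, one.surgical.zeta_p)
        direct = solve_scenario(reference_preop, reference_case,
                                Scenario.OPTIMIZED_PMA, zeta_pair=pair)
        assert direct.surgical.r == pytest.approx(one.surgical.r, abs=1e-10)
        assert direct.T_po_a == pytest.approx(one.T_po_a, rel=1e-10)

    def test_returned_objective_is_minimal_among_draws(self, optimized):
        hist = [h["objective"] for h in optimized.provenance["history"]
                if h["objective"] is not None]
        assert optimized.provenance["best_objective"] == pytest.approx(min(hist))
        assert max(optimized.T_po_a, optimized.T_po_p) <= (
            optimized.provenance["best_objective"] * 1.02 + 1e-12)

    def test_more_draws_never_worse(self, reference_preop, reference_case):
        few = optimize_pma(reference_preop, reference_case, seed=2, n_draws=15)
        many = optimize_pma(reference_preop, reference_case, seed=2, n_draws=45)
        assert (many.provenance["best_objective"]
                <= few.provenance["best_objective"] + 1e-12)

    def test_deterministic(self, reference_preop, reference_case):
        a = optimize_pma(reference_preop, reference_case, seed=4, n_draws=20)
        b = optimize_pma(reference_preop, reference_case, seed=4, n_draws=20)
        assert a.surgical.r == b.surgical.r and a.IPD_po == b.IPD_po

    def test_missing_zeta_pair_rejected(self, reference_preop, reference_case):
        with pytest.raises(ValueError):
            solve_scenario(reference_preop, reference_case, Scenario.OPTIMIZED_PMA)


class TestFixedPoint:
    def test_preop_is_fixed_point_when_target_equals_tenting(self):
        """With the coaptation target at the preoperative tip depth of a
        symmetric patient, the preoperative state solves the system at
        r = 0 and u = 0."""
        meas = ValveMeasurements(
            MAD_pre=40.0, IPD_pre=40.0, TH_pre=8.0, TH_opt=5.0,
            delta_a=math.radians(40.0), delta_p=math.radians(40.0),
            h_a=40.0, h_p=40.0, l_a=16.0, l_p=16.0, B=500.0)
        cfg = _build_geometry(meas, 0.3, 0.3)
        th = float(cfg.b_a[1])
        # close the preoperative valve: annular width equal to the two tip
        # abscissae so the leaflets already coapt before surgery
        meas2 = meas.with_(MAD_pre=2 * float(cfg.b_a[0]),
                           TH_pre=th + 0.01, TH_opt=th * 0.999999)
        cfg2 = _build_geometry(meas2, 0.3, 0.3)
        meas2 = meas2.with_(IPD_pre=cfg2.interpapillary_distance)
        pre = finalize_preop(cfg2, meas2)
        meas3 = meas2.with_(TH_opt=float(pre.system.b_a[1]))
        z = (pre.system.theta_a, pre.system.theta_p,
             pre.system.alpha_a, pre.system.alpha_p, 0.0, 0.0, 0.0)
        res = postop_residuals(z, pre, meas3, 0.0, 0.0)
        assert np.max(np.abs(res)) < 1e-6


class TestRaOnly:
    def test_tips_level_and_muscles_motionless(self, reference_preop, reference_case):
        ra = solve_scenario(reference_preop, reference_case, Scenario.RA_ONLY)
        assert ra.system.b_a[1] == pytest.approx(ra.system.b_p[1], abs=1e-7)
        assert np.allclose(ra.surgical.u_a, 0.0) and np.allclose(ra.surgical.u_p, 0.0)
        assert ra.surgical.r == pytest.approx(ra.surgical.r_a + ra.surgical.r_p)
        assert ra.residual_norm < 1e-6
        # severe tethering: a coaptation gap persists above the target height
        assert ra.provenance["coaptation_gap"] > 0.0
        assert ra.system.b_a[1] > reference_case.TH_opt

    def test_tethering_increases_chordal_state(self, reference_preop, reference_case):
        ra = solve_scenario(reference_preop, reference_case, Scenario.RA_ONLY)
        ind = indicators(reference_preop, ra)
        assert ind.Tr_a >= 1.0 and ind.Tr_p >= 1.0
        assert ind.lr_a >= 1.0 and ind.lr_p >= 1.0


class TestCompletePma:
    def test_prescribed_distance_honoured_when_reachable(self):
        meas = ValveMeasurements.reference_case().with_(
            h_a=30.0, h_p=28.0, IPD_pre=30.0)
        pre = identify_preop(meas, seed=1, mode="best", max_iter=400, symmetric=True)
        po = solve_scenario(pre, meas, Scenario.COMPLETE_PMA, ipd_target=10.0)
        assert abs(po.IPD_po - 10.0) < 1e-8
        assert po.residual_norm < 1e-8

    def test_unreachable_prescription_raises_by_default(self, reference_preop,
                                                        reference_case):
        from mvelastica.postop import PostopSolveError
        with pytest.raises(PostopSolveError, match="achievable"):
            solve_scenario(reference_preop, reference_case, Scenario.COMPLETE_PMA,
                           ipd_target=10.0)

    def test_nearest_fallback_reports_achieved_distance(self, reference_preop,
                                                        reference_case):
        po = solve_scenario(reference_preop, reference_case, Scenario.COMPLETE_PMA,
                            ipd_target=10.0, on_unreachable="nearest")
        assert po.provenance["ipd_achieved"] > 10.0
        assert po.IPD_po == pytest.approx(po.provenance["ipd_achieved"], abs=1e-6)


class TestIndicators:
    def test_identity_when_postop_equals_preop(self, reference_preop, optimized):
        same = dataclasses.replace(
            optimized,
            M_po_a=reference_preop.M_pre_a, M_po_p=reference_preop.M_pre_p,
            T_po_a=reference_preop.T_pre_a, T_po_p=reference_preop.T_pre_p,
            lam_po_a=reference_preop.lam_pre_a, lam_po_p=reference_preop.lam_pre_p)
        ind = indicators(reference_preop, same)
        for v in dataclasses.astuple(ind):
            assert v == pytest.approx(1.0, rel=1e-12)

    def test_ratios_are_homogeneous(self, reference_preop, reference_case, optimized):
        doubled = dataclasses.replace(reference_preop,
                                      M_pre_a=2 * reference_preop.M_pre_a)
        ind0 = indicators(reference_preop, optimized)
        ind1 = indicators(doubled, optimized)
        assert ind1.Mr_a == pytest.approx(ind0.Mr_a / 2, rel=1e-12)
        assert ind1.Mr_p == ind0.Mr_p

    def test_zero_denominator_rejected(self, reference_preop, optimized):
        broken = dataclasses.replace(reference_preop, M_pre_a=0.0)
        with pytest.raises(ZeroDivisionError):
            indicators(broken, optimized)
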