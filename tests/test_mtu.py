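"""Hill-type MTU mechanics: tendon curve values, pennation geometry,
force-velocity inversion, simulation oracles, ligament and moment assembly."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from gaitmtu import hill
from gaitmtu import io as gio
from gaitmtu import mtu as M
from gaitmtu.datatypes import HFLParams, MTUParams, MTUTrace
from gaitmtu.muscles import MUSCLES
from gaitmtu.synthetic import params_from_vector


def _params(**kw) -> MTUParams:
    base = dict(name="test", F_max=1000.0, l_opt=0.10, l_sl=0.25, K_sh=3.0,
                lambda_ref=0.05, theta0=0.0, w=0.56, v_max=10.0, FT=0.5)
    base.update(kw)
    return MTUParams(**base)


class TestTendonForce:
    def test_participant_fixture_reaches_f_max_at_reference_strain(self):
        vec = gio.load_participant(1)
        ta = vec.muscle_block("TA")
        p = _params(F_max=ta["F_max"], K_sh=ta["K_sh"],
                    lambda_ref=ta["lambda_ref"])
        assert M.tendon_force(ta["lambda_ref"], p) == pytest.approx(477.0)

    def test_all_participant_fixtures_normalize(self):
        """F(lambda_ref) = F_max independently of the shape factor."""
        for n in range(1, 6):
            vec = gio.load_participant(n)
            for m in vec.muscles:
                b = vec.muscle_block(m)
                p = _params(F_max=b["F_max"], K_sh=b["K_sh"],
                            lambda_ref=b["lambda_ref"])
                assert M.tendon_force(b["lambda_ref"], p) == pytest.approx(
                    b["F_max"], rel=1e-12)
                assert M.tendon_force(0.0, p) == 0.0

    def test_slack_tendon_carries_no_force(self):
        assert M.tendon_force(-0.01, _params()) == 0.0

    def test_hand_evaluated_value(self):
        # F_max=1000, K_sh=3, lambda = lambda_ref/2:
        # 1000*(e^1.5-1)/(e^3-1) = 182.43 N
        p = _params(F_max=1000.0, K_sh=3.0, lambda_ref=0.05)
        assert M.tendon_force(0.025, p) == pytest.approx(182.43, abs=0.01)

    def test_strictly_increasing(self):
        p = _params()
        lam = np.linspace(1e-6, 0.1, 200)
        f = M.tendon_force(lam, p)
        assert np.all(np.diff(f) > 0)


class TestPennation:
    def test_optimal_length_gives_reference_angle(self):
        p = _params(theta0=math.radians(20.0))
        assert M.pennation_angle(p.l_opt, p) == pytest.approx(p.theta0)

    def test_zero_reference_angle_stays_zero(self):
        p = _params(theta0=0.0)
        assert M.pennation_angle(0.03, p) == 0.0

    def test_geometric_minimum_gives_ninety_degrees(self):
        p = _params(l_opt=0.10, theta0=math.radians(30.0))
        assert M.pennation_angle(0.05, p) == pytest.approx(math.pi / 2)

    def test_below_minimum_clamps_with_warning(self):
        p = _params(l_opt=0.10, theta0=math.radians(30.0))
        with pytest.warns(RuntimeWarning, match="clamped"):
            th = M.pennation_angle(0.04, p)
        assert th < math.pi / 2

    def test_muscle_width_is_conserved(self):
        p = _params(theta0=math.radians(25.0))
        l = np.linspace(0.06, 0.15, 50)
        width = l * np.sin(M.pennation_angle(l, p))
        assert np.max(np.abs(width - width[0])) < 1e-12


class TestCeForce:
    def test_zero_activation_zero_active_force(self):
        p = _params()
        f_ce, _ = M.ce_force(0.0, 0.08, -0.1, p)
        assert f_ce == 0.0

    def test_isometric_optimal_gives_f_max(self):
        p = _params()
        f_ce, f_pe = M.ce_force(1.0, p.l_opt, 0.0, p)
        assert f_ce == pytest.approx(p.F_max)
        assert f_pe == 0.0

    def test_maximal_shortening_gives_zero(self):
        p = _params()
        f_ce, _ = M.ce_force(1.0, p.l_opt, -p.v_max_abs, p)
        assert f_ce == 0.0

    def test_pe_engages_only_above_optimal(self):
        p = _params()
        assert M.ce_force(0.0, 0.99 * p.l_opt, 0.0, p)[1] == 0.0
        assert M.ce_force(0.0, 1.10 * p.l_opt, 0.0, p)[1] > 0.0


class TestSolveCeVelocity:
    def test_isometric_equilibrium(self):
        """When the tendon force exactly matches the isometric muscle force
        the fascicle velocity is zero."""
        p = _params(theta0=math.radians(10.0))
        a, l_ce = 0.6, 0.095
        cosT = math.cos(M.pennation_angle(l_ce, p))
        target = (a * p.F_max * hill.force_length(l_ce, p.l_opt, p.w)
                  + hill.parallel_force(l_ce, p.l_opt, p.w, p.F_max)) * cosT
        # invert the tendon curve for the strain carrying that force
        lam = brentq(lambda s: M.tendon_force(s, p) - target, 0.0, 0.2)
        l_mtc = p.l_sl * (1 + lam) + l_ce * cosT
        assert M.solve_ce_velocity(a, l_ce, l_mtc, p) == pytest.approx(0.0, abs=1e-9)

    def test_under_loaded_tendon_shortens(self):
        p = _params()
        a, l_ce = 0.8, 0.10
        l_mtc = p.l_sl * 1.001 + l_ce  # barely taut tendon
        assert M.solve_ce_velocity(a, l_ce, l_mtc, p) < 0.0

    def test_analytic_inverse_matches_bisection(self):
        """100 random valid states: analytic force-velocity inversion agrees
        with a brute-force bisection to < 1e-6 v_max."""
        rng = np.random.default_rng(0)
        p = _params(theta0=math.radians(12.0))
        checked = 0
        while checked < 100:
            a = rng.uniform(0.05, 1.0)
            l_ce = rng.uniform(0.7, 1.3) * p.l_opt
            lam = rng.uniform(0.0, 1.2) * p.lambda_ref
            cosT = math.cos(M.pennation_angle(l_ce, p))
            l_mtc = p.l_sl * (1 + lam) + l_ce * cosT
            try:
                v = M.solve_ce_velocity(a, l_ce, l_mtc, p)
            except M.SimulationError:
                continue
            checked += 1
            # independent bisection on the monotone force-velocity curve
            f_req = (M.tendon_force(lam, p) / cosT
                     - hill.parallel_force(l_ce, p.l_opt, p.w, p.F_max)) \
                / (max(a, hill.ACTIVATION_FLOOR) * p.F_max
                   * hill.force_length(l_ce, p.l_opt, p.w))
            lo, hi = -p.v_max_abs, p.v_max_abs
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if hill.force_velocity(mid, p.v_max_abs) < f_req:
                    lo = mid
                else:
                    hi = mid
            assert abs(v - 0.5 * (lo + hi)) < 1e-6 * p.v_max_abs

    def test_overloaded_passive_muscle_reports_no_root(self):
        p = _params()
        # inactive muscle, tendon stretched far beyond its force ceiling
        with pytest.raises(M.SimulationError, match="no fascicle velocity"):
            M.solve_ce_velocity(0.0, p.l_opt, p.l_sl * 1.3 + p.l_opt, p)


class TestSimulateMtu:
    def test_slack_inactive_muscle_rests_at_optimal_length(self):
        p = _params()
        t = np.arange(125) / 125.0
        l_mtc = np.full_like(t, 0.9 * p.l_sl)  # always slack
        tr = M.simulate_mtu(t, l_mtc, np.zeros_like(t), p)
        assert np.all(tr.F_SE == 0.0)
        assert np.allclose(tr.l_CE, p.l_opt, atol=1e-3)

    def test_constant_inputs_converge_to_static_equilibrium(self):
        p = _params(theta0=math.radians(15.0))
        t = np.arange(125) / 125.0
        a = 0.5
        l_mtc = np.full_like(t, p.l_sl * 1.02 + p.l_opt * math.cos(p.theta0))
        tr = M.simulate_mtu(t, l_mtc, np.full_like(t, a), p)

        def g(l_ce):
            cosT = math.cos(M.pennation_angle(l_ce, p, warn=False))
            lam = (l_mtc[0] - l_ce * cosT - p.l_sl) / p.l_sl
            fm = (a * p.F_max * hill.force_length(l_ce, p.l_opt, p.w)
                  + hill.parallel_force(l_ce, p.l_opt, p.w, p.F_max))
            return M.tendon_force(lam, p) - fm * cosT

        l_eq = brentq(g, 0.5 * p.l_opt, 1.5 * p.l_opt)
        assert abs(tr.l_CE[-1] - l_eq) < 1e-4 * p.l_opt

    def test_rigid_tendon_limit(self, full_subject):
        """With a near-rigid tendon and a loaded muscle the fascicle tracks
        (l_MTC - l_sl)/cos(theta) to within 1% of l_opt. TA is used because
        its short tendon keeps the residual elastic stretch (which scales
        with l_sl/l_opt) well inside the budget."""
        dataset, truth, _ = full_subject
        params, _ = params_from_vector(truth.morphology)
        p = dataclasses.replace(params["TA"], lambda_ref=0.002)
        a = np.full_like(dataset.time, 0.5)  # keep the tendon taut
        tr = M.simulate_mtu(dataset.time, dataset.mtu_lengths["TA"], a, p)
        pred = (dataset.mtu_lengths["TA"] - p.l_sl) / np.cos(tr.theta)
        assert np.max(np.abs(tr.l_CE - pred)) < 0.01 * p.l_opt

    def test_force_balance_residual_at_every_output_sample(self, full_truth_simulation):
        _, truth, params, traces, _ = full_truth_simulation
        for m, tr in traces.items():
            p = params[m]
            a = truth.activations[m]
            c = hill.CE_DAMPING * p.F_max / p.v_max_abs
            f_m = (a * p.F_max * hill.force_length(tr.l_CE, p.l_opt, p.w)
                   * hill.force_velocity(tr.v_CE, p.v_max_abs) + tr.F_PE
                   + c * tr.v_CE)
            resid = np.abs(tr.F_SE - f_m * np.cos(tr.theta))
            assert np.max(resid) < 1e-6 * p.F_max, m

    def test_muscle_width_conserved_along_trace(self, full_truth_simulation):
        _, _, params, traces, _ = full_truth_simulation
        for m, tr in traces.items():
            width = tr.l_CE * np.sin(tr.theta)
            expected = params[m].l_opt * math.sin(params[m].theta0)
            assert np.max(np.abs(width - expected)) < 1e-9

    def test_fast_path_agrees_with_stiff_variable_step_solver(self, full_subject):
        dataset, truth, _ = full_subject
        params, _ = params_from_vector(truth.morphology)
        for m in ("TA", "VAS", "HAM"):
            fast = M.simulate_mtu(dataset.time, dataset.mtu_lengths[m],
                                  truth.activations[m], params[m])
            ref = M.simulate_mtu(dataset.time, dataset.mtu_lengths[m],
                                 truth.activations[m], params[m],
                                 method="lsoda")
            assert np.max(np.abs(fast.l_CE - ref.l_CE)) < 5e-3 * params[m].l_opt

    def test_elastic_elements_do_no_net_work_over_a_periodic_cycle(self, full_truth_simulation):
        """Net tendon + parallel-elastic work over the steady-state cycle is
        below 1% of the contractile work."""
        _, _, params, traces, _ = full_truth_simulation
        for m in ("SOL", "GAS", "VAS"):
            tr = traces[m]
            dt = tr.time[1] - tr.time[0]
            l_se = np.cos(tr.theta) * tr.l_CE  # via l_mtc - l_se identity
            # elastic length rates from periodic central differences
            def ddt(x):
                return (np.roll(x, -1) - np.roll(x, 1)) / (2 * dt)
            w_pe = np.sum(tr.F_PE * ddt(tr.l_CE)) * dt
            w_se = np.sum(tr.F_SE * ddt(tr.lam) * params[m].l_sl) * dt
            w_ce = np.sum(np.abs(tr.F_CE * tr.v_CE)) * dt
            assert abs(w_pe + w_se) < 0.01 * w_ce, m


class TestForceVelocityShape:
    def test_power_optimal_velocity_closed_form(self):
        """The shortening speed maximizing CE power equals
        (sqrt(1+K)-1)/K of v_max, landing near 0.30 v_max."""
        for K in (4.0, 4.5, 5.0):
            closed = hill.optimal_power_velocity(K)
            res = minimize_scalar(
                lambda s: -s * (1 - s) / (1 + K * s), bounds=(0, 1),
                method="bounded")
            assert closed == pytest.approx(res.x, abs=1e-5)
            assert 0.28 <= closed <= 0.32

    def test_eccentric_branch_continuous_and_saturating(self):
        p = _params()
        v = np.linspace(-p.v_max_abs, p.v_max_abs, 500)
        f = hill.force_velocity(v, p.v_max_abs)
        assert np.all(np.diff(f) >= 0)
        assert f[0] == 0.0
        assert hill.force_velocity(0.0, p.v_max_abs) == pytest.approx(1.0)
        assert np.max(f) < hill.FV_N


class TestHflTorque:
    def test_zero_at_engagement_angle(self):
        assert M.hfl_torque(0.04, HFLParams(193.0, 0.04)) == 0.0

    def test_disengaged_when_flexed(self):
        assert M.hfl_torque(0.24, HFLParams(193.0, 0.04)) == 0.0

    def test_linear_flexion_torque_when_extended(self):
        # participant-1 stiffness: 0.1 rad past engagement -> +19.3 N m
        assert M.hfl_torque(-0.06, HFLParams(193.0, 0.04)) == pytest.approx(19.3)


class TestJointMoments:
    @staticmethod
    def _trace(name, F, n=10):
        z = np.zeros(n)
        return MTUTrace(name=name, time=np.arange(n) / 125.0, l_CE=z + 0.1,
                        v_CE=z, theta=z, F_CE=z + F, F_PE=z,
                        F_SE=np.full(n, F), lam=z)

    def test_single_muscle_torque(self):
        tau = M.joint_moments({"TA": self._trace("TA", 100.0)},
                              {"TA": {"ankle": np.full(10, 0.05)}})
        assert np.allclose(tau["ankle"], 5.0)

    def test_zero_force_zero_moment(self):
        tau = M.joint_moments({"TA": self._trace("TA", 0.0)},
                              {"TA": {"ankle": np.full(10, 0.05)}})
        assert np.allclose(tau["ankle"], 0.0)

    def test_sign_flip_affects_only_that_muscle(self):
        traces = {"TA": self._trace("TA", 100.0),
                  "SOL": self._trace("SOL", 200.0)}
        arms = {"TA": {"ankle": np.full(10, 0.04)},
                "SOL": {"ankle": np.full(10, -0.05)}}
        tau1 = M.joint_moments(traces, arms)["ankle"]
        arms2 = {"TA": {"ankle": -arms["TA"]["ankle"]},
                 "SOL": {"ankle": arms["SOL"]["ankle"]}}
        tau2 = M.joint_moments(traces, arms2)["ankle"]
        assert np.allclose(tau2 - tau1, -2 * 100.0 * 0.04)

    def test_missing_moment_arm_is_named_error(self):
        with pytest.raises(KeyError, match="TA"):
            M.joint_moments({"TA": self._trace("TA", 1.0)}, {})
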