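"""Metabolic model: rate-component identities, mass formula, whole-body
cost closed forms, phase accounting, and efficiency properties."""

import numpy as np
import pytest

from gaitmtu import energetics as en
from gaitmtu.datatypes import GaitEvents, MTUParams, MTUTrace, SubjectScalars
from gaitmtu.datatypes import GRAVITY


def _params(**kw) -> MTUParams:
    base = dict(name="test", F_max=1000.0, l_opt=0.10, l_sl=0.25, K_sh=3.0,
                lambda_ref=0.05, theta0=0.0, w=0.56, v_max=10.0, FT=0.5)
    base.update(kw)
    return MTUParams(**base)


class TestUmbergerRate:
    def test_resting_muscle_consumes_nothing(self):
        comps = en.umberger_rate(0.0, 0.0, 0.10, 0.0, 0.0, _params())
        for k in ("h_A", "h_M", "h_SL", "w_CE"):
            assert comps[k] == 0.0

    def test_isometric_sample_has_no_velocity_terms(self):
        comps = en.umberger_rate(0.8, 0.8, 0.10, 0.0, 500.0, _params())
        assert comps["w_CE"] == 0.0
        assert comps["h_SL"] == 0.0
        assert comps["h_A"] > 0 and comps["h_M"] > 0

    def test_work_rate_identity(self):
        """Shortening at 100 N and 0.1 m/s in a 0.5 kg muscle is 20 W/kg."""
        # rho F l / sigma = 0.5 kg  ->  F_max = 0.5 sigma / (rho l_opt)
        F_max = 0.5 * en.SIGMA_MUSCLE / (en.RHO_MUSCLE * 0.10)
        p = _params(F_max=F_max)
        assert en.muscle_mass(p) == pytest.approx(0.5)
        comps = en.umberger_rate(1.0, 1.0, 0.10, -0.1, 100.0, p)
        assert comps["w_CE"] == pytest.approx(20.0)

    def test_negative_work_excluded(self):
        comps = en.umberger_rate(1.0, 1.0, 0.10, +0.1, 100.0, _params())
        assert comps["w_CE"] == 0.0
        assert comps["h_SL"] > 0.0  # lengthening heat remains

    def test_all_components_nonnegative_and_total_dominates_work(self):
        rng = np.random.default_rng(0)
        p = _params()
        for _ in range(50):
            u, a = sorted(rng.random(2))
            comps = en.umberger_rate(u, a, rng.uniform(0.07, 0.13),
                                     rng.uniform(-0.5, 0.5),
                                     rng.uniform(0, 800), p)
            assert all(comps[k] >= 0 for k in ("h_A", "h_M", "h_SL", "w_CE"))
            assert comps["total"] >= comps["w_CE"]


class TestMuscleMass:
    def test_hand_value(self):
        # 1059.7 * 1000 * 0.10 / 0.25e6 = 0.42388 kg
        assert en.muscle_mass(_params(F_max=1000.0, l_opt=0.10)) == \
            pytest.approx(0.42388, abs=1e-5)

    def test_zero_strength_zero_mass(self):
        assert en.muscle_mass(_params(F_max=0.0)) == 0.0

    def test_linearity_in_strength(self):
        assert en.muscle_mass(_params(F_max=2000.0)) == \
            pytest.approx(2 * en.muscle_mass(_params(F_max=1000.0)))


class TestWholeBodyCost:
    scal = SubjectScalars(body_mass=70.0, height=1.75, walking_speed=1.25,
                          basal_rate=1.5, gait_cycle_duration=1.1)

    def test_silent_muscles_give_basal_only_closed_form(self):
        T = 1.1
        c, mcot = en.whole_body_cost({"SOL": 0.0}, {"SOL": 0.7},
                                     self.scal, T)
        assert c == pytest.approx(70.0 * 1.5 * T - 2 * 0.7 * 1.5 * T)
        # with no muscle mass at all, MCOT reduces to Ebas/(g v)
        c0, mcot0 = en.whole_body_cost({}, {}, self.scal, T)
        assert mcot0 == pytest.approx(1.5 / (GRAVITY * 1.25))

    def test_zero_energy_muscle_only_shifts_basal_billing(self):
        T = 1.1
        c1, _ = en.whole_body_cost({"A": 50.0}, {"A": 1.0}, self.scal, T)
        c2, _ = en.whole_body_cost({"A": 50.0, "B": 0.0},
                                   {"A": 1.0, "B": 0.8}, self.scal, T)
        # the new muscle's (bilateral) mass leaves the basal pool
        assert c2 - c1 == pytest.approx(-2 * 0.8 * 1.5 * T)

    def test_doubling_window_doubles_cost_for_stationary_rates(self):
        c1, _ = en.whole_body_cost({"A": 30.0}, {"A": 1.0}, self.scal, 1.0)
        c2, _ = en.whole_body_cost({"A": 60.0}, {"A": 1.0}, self.scal, 2.0)
        assert c2 == pytest.approx(2 * c1)

    def test_additive_and_order_invariant(self):
        T = 1.0
        e = {"A": 10.0, "B": 20.0, "C": 5.0}
        m = {"A": 0.5, "B": 0.7, "C": 0.2}
        c1, _ = en.whole_body_cost(e, m, self.scal, T)
        e2 = dict(reversed(list(e.items())))
        m2 = dict(reversed(list(m.items())))
        c2, _ = en.whole_body_cost(e2, m2, self.scal, T)
        assert c1 == c2

    def test_muscle_mass_exceeding_body_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            en.whole_body_cost({"A": 0.0}, {"A": 40.0}, self.scal, 1.0)


def _events(T=1.0):
    return GaitEvents(heel_strikes=np.array([0.0, T]),
                      toe_offs=np.array([0.62 * T]),
                      contra_heel_strikes=np.array([0.5 * T]),
                      contra_toe_offs=np.array([0.12 * T]))


class TestPhaseFractions:
    def test_uniform_rate_gives_duration_fractions(self):
        t = np.arange(1000) / 1000.0
        f = en.phase_fractions(t, np.ones_like(t), _events())
        assert f[0] == pytest.approx(0.12 + 0.12, abs=0.01)  # both DS
        assert f[1] == pytest.approx(0.38, abs=0.01)
        assert f[2] == pytest.approx(0.38, abs=0.01)
        assert sum(f) == pytest.approx(1.0, abs=1e-9)

    def test_swing_only_rate(self):
        t = np.arange(1000) / 1000.0
        rate = np.where(t >= 0.62, 1.0, 0.0)
        assert en.phase_fractions(t, rate, _events()) == \
            pytest.approx((0.0, 0.0, 1.0))

    def test_walking_fixture_sums_to_one(self, full_truth_simulation):
        dataset, truth, params, traces, _ = full_truth_simulation
        masses = {m: en.muscle_mass(params[m]) for m in traces}
        total = sum(
            masses[m] * en.umberger_rate(truth.drive_signals[m],
                                         truth.activations[m], tr.l_CE,
                                         tr.v_CE, tr.F_CE, params[m])["total"]
            for m, tr in traces.items())
        f = en.phase_fractions(dataset.time, total, dataset.events)
        assert all(0 <= x <= 1 for x in f)
        assert sum(f) == pytest.approx(1.0, abs=1e-9)


class TestEfficiency:
    @staticmethod
    def _const_trace(p, F, v, n=100):
        t = np.arange(n) / 125.0
        z = np.zeros(n)
        return MTUTrace(name=p.name, time=t, l_CE=z + p.l_opt, v_CE=z + v,
                        theta=z, F_CE=z + F, F_PE=z, F_SE=z + F, lam=z)

    def test_isometric_cycle_has_zero_efficiency(self):
        p = _params()
        tr = self._const_trace(p, 500.0, 0.0)
        rate = {p.name: np.full(100, 30.0)}
        assert en.positive_work_efficiency({p.name: tr}, rate,
                                           {p.name: p}) == 0.0

    def test_ratio_identity(self):
        """Work rate w against total rate 4w gives efficiency 0.25."""
        p = _params()
        m_i = en.muscle_mass(p)
        F, v = 100.0, -0.1
        w = -F * v / m_i
        tr = self._const_trace(p, F, v)
        rate = {p.name: np.full(100, 4 * w)}
        assert en.positive_work_efficiency({p.name: tr}, rate,
                                           {p.name: p}) == pytest.approx(0.25)

    def test_efficiency_peaks_near_017_vmax(self):
        """Steady shortening at 0.17 v_max is more efficient than very slow
        or very fast shortening (the classic efficiency optimum)."""
        from gaitmtu import hill

        p = _params()

        def eff(frac):
            v = -frac * p.v_max_abs
            F = p.F_max * hill.force_velocity(v, p.v_max_abs)
            comps = en.umberger_rate(1.0, 1.0, p.l_opt, v, F, p)
            return comps["w_CE"] / comps["total"]

        assert eff(0.17) > eff(0.02)
        assert eff(0.17) > eff(0.9)

    def test_efficiency_never_exceeds_one(self, full_truth_simulation):
        _, truth, params, traces, _ = full_truth_simulation
        rates = {m: en.umberger_rate(truth.drive_signals[m],
                                     truth.activations[m], tr.l_CE, tr.v_CE,
                                     tr.F_CE, params[m])["total"]
                 for m, tr in traces.items()}
        eff = en.positive_work_efficiency(traces, rates, params)
        assert 0.0 < eff <= 1.0
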