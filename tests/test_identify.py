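"""Identification stage: cost functions, bounds construction, candidate
evaluation, and the dual-objective genetic search."""

import dataclasses

import numpy as np
import pytest

from gaitmtu import identify as ident
from gaitmtu import synthetic as syn
from gaitmtu.datatypes import GaitDataset, GaitEvents, SubjectScalars


class TestKineticCost:
    def test_perfect_fit(self):
        tau = {"ankle": np.sin(np.linspace(0, 6, 100))}
        c, r2 = ident.kinetic_cost(tau, tau)
        assert c == 0.0
        assert r2["ankle"] == 1.0

    def test_mean_predictor_scores_zero_r2(self):
        exp = {"ankle": np.sin(np.linspace(0, 6, 100))}
        mod = {"ankle": np.full(100, exp["ankle"].mean())}
        c, r2 = ident.kinetic_cost(mod, exp)
        assert r2["ankle"] == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0)

    def test_noise_at_known_residual_ratio(self):
        rng = np.random.default_rng(0)
        exp = np.sin(np.linspace(0, 6, 2000))
        noise = rng.normal(0, 1.0, 2000)
        # scale the noise so SS_res/SS_tot is exactly 0.1
        ss_tot = np.sum((exp - exp.mean()) ** 2)
        noise *= np.sqrt(0.1 * ss_tot / np.sum(noise ** 2))
        c, _ = ident.kinetic_cost({"a": exp + noise}, {"a": exp})
        assert c == pytest.approx(0.1, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ident.kinetic_cost({"a": np.zeros(10)}, {"a": np.ones(10)})


class TestFmae:
    mask = np.ones(100, dtype=bool)

    def test_identical_signals(self):
        x = np.sin(np.linspace(0, 6, 100))
        assert ident.fmae(x, x, self.mask) == 0.0

    def test_constant_offset_identity(self):
        x = np.linspace(-20.0, 20.0, 100)  # range 40
        assert ident.fmae(x + 2.0, x, self.mask) == pytest.approx(2.0 / 40.0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ident.fmae(np.zeros(100), np.ones(100), self.mask)


class TestBuildBounds:
    def test_tendon_material_bounds_are_fixed(self, full_subject):
        dataset, _, bounds = full_subject
        for m in bounds.muscles:
            i = list(bounds.muscles).index(m)
            assert bounds.lower[4 * i + 2] == 2.0
            assert bounds.upper[4 * i + 2] == 5.0
            assert bounds.lower[4 * i + 3] == 0.02
            assert bounds.upper[4 * i + 3] == 0.09

    def test_ligament_stiffness_ceiling_formula(self):
        """K_HFL upper bound = 2 max(tau_hip) / |min(theta_hip)|."""
        n = 100
        t = np.arange(n) / 125.0
        theta = np.linspace(-0.3, 0.3, n)
        ds = GaitDataset(
            time=t, joint_angles={"hip": theta},
            mtu_lengths={"ILL": np.full(n, 0.19)},
            moment_arms={"ILL": {"hip": np.full(n, 0.035)}},
            joint_moments={"hip": np.linspace(-30, 60.0, n)},
            emg_time=t, emg={},
            events=GaitEvents(heel_strikes=np.array([0.0, n / 125.0]),
                              toe_offs=np.array([0.5]),
                              contra_heel_strikes=np.array([0.4]),
                              contra_toe_offs=np.array([0.1])),
            scalars=SubjectScalars(70.0, 1.75, 1.25, 1.5, n / 125.0))
        b = ident.build_bounds(ds, {"ILL": 800.0}, include_ligament=True)
        assert b.meta["K_HFL_upper"] == pytest.approx(2 * 60.0 / 0.3)
        assert b.upper[-1] == pytest.approx(0.3)  # engagement angle cap
        assert b.lower[-1] == pytest.approx(-np.pi / 18)

    def test_wider_force_length_curve_widens_scale_interval(self, full_subject, monkeypatch):
        from gaitmtu import muscles as mus

        dataset, _, _ = full_subject
        ref = {m: mus.MUSCLES[m].F_max_ref for m in dataset.muscles}
        b_narrow = ident.build_bounds(dataset, ref, include_ligament=False)
        wide = {m: dataclasses.replace(s, w=min(0.95, s.w + 0.2))
                for m, s in mus.MUSCLES.items()}
        monkeypatch.setattr(ident, "MUSCLES", wide)
        b_wide = ident.build_bounds(dataset, ref, include_ligament=False)
        for m in b_narrow.muscles:
            lo_n, hi_n = b_narrow.meta["length_scale_intervals"][m]
            lo_w, hi_w = b_wide.meta["length_scale_intervals"][m]
            assert lo_w <= lo_n and hi_w >= hi_n

    def test_infeasible_sweep_is_named_error(self):
        n = 100
        t = np.arange(n) / 125.0
        theta = np.linspace(-2.5, 2.5, n)  # absurd excursion
        ds = GaitDataset(
            time=t, joint_angles={"ankle": theta},
            mtu_lengths={"TA": 0.32 - 0.08 * theta},
            moment_arms={"TA": {"ankle": np.full(n, 0.08)}},
            joint_moments={"ankle": theta},
            emg_time=t, emg={},
            events=GaitEvents(heel_strikes=np.array([0.0, n / 125.0]),
                              toe_offs=np.array([0.5]),
                              contra_heel_strikes=np.array([0.4]),
                              contra_toe_offs=np.array([0.1])),
            scalars=SubjectScalars(70.0, 1.75, 1.25, 1.5, n / 125.0))
        with pytest.raises(ValueError, match="TA"):
            ident.build_bounds(ds, {"TA": 600.0}, include_ligament=False)


class TestEvaluateCandidate:
    def test_truth_self_consistency(self, ankle_subject_noiseless):
        dataset, truth, _ = ankle_subject_noiseless
        _, c_kin, diag = ident.evaluate_candidate(
            truth.morphology, dataset, truth.activations,
            drives=truth.drive_signals)
        assert c_kin < 1e-3
        assert not diag["failed"]

    def test_evaluation_is_deterministic(self, ankle_subject_noiseless):
        dataset, truth, _ = ankle_subject_noiseless
        r1 = ident.evaluate_candidate(truth.morphology, dataset,
                                      truth.activations)
        r2 = ident.evaluate_candidate(truth.morphology, dataset,
                                      truth.activations)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_weak_muscle_corner(self, ankle_subject_noiseless):
        """All strengths at the lower bound: metabolically cheaper than the
        truth but kinetically worse (the front's lower-left corner)."""
        dataset, truth, bounds = ankle_subject_noiseless
        weak = truth.morphology.values.copy()
        for i in range(len(bounds.muscles)):
            weak[4 * i] = bounds.lower[4 * i]
        weak_vec = dataclasses.replace(truth.morphology, values=weak)
        c_met_t, c_kin_t, _ = ident.evaluate_candidate(
            truth.morphology, dataset, truth.activations)
        c_met_w, c_kin_w, _ = ident.evaluate_candidate(
            weak_vec, dataset, truth.activations)
        assert c_met_w < c_met_t
        assert c_kin_w > c_kin_t

    def test_failure_returns_penalty_not_exception(self, ankle_subject_noiseless):
        dataset, truth, _ = ankle_subject_noiseless
        bad_acts = {m: np.full_like(dataset.time, np.nan)
                    for m in truth.morphology.muscles}
        c_met, c_kin, diag = ident.evaluate_candidate(
            truth.morphology, dataset, bad_acts)
        assert diag["failed"]
        assert c_kin == ident.PENALTY_C_KIN
        basal = (dataset.scalars.body_mass * dataset.scalars.basal_rate
                 * dataset.time.size * dataset.dt)
        assert c_met == pytest.approx(ident.PENALTY_BASAL_FACTOR * basal)


@pytest.fixture(scope="module")
def toy_run(ankle_subject_noiseless):
    dataset, truth, bounds = ankle_subject_noiseless
    cfg = ident.GAConfig(population_size=64, generations=20)
    front, history = ident.run_identification(
        dataset, truth.activations, bounds, cfg, seed=5,
        drives=truth.drive_signals, return_history=True)
    return front, history


class TestRunIdentification:
    def test_front_is_nondominated_by_brute_force(self, toy_run):
        front, _ = toy_run
        F = np.array([[s.C_met, s.C_kin] for s in front])
        n = len(front)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dominates = (np.all(F[j] <= F[i]) and np.any(F[j] < F[i]))
                assert not dominates

    def test_front_large_enough_and_tradeoff_monotone(self, toy_run):
        front, _ = toy_run
        assert len(front) >= 5
        order = np.argsort([s.C_met for s in front])
        c_kin_sorted = np.array([front[i].C_kin for i in order])
        assert np.all(np.diff(c_kin_sorted) <= 1e-12)

    def test_hypervolume_improves_monotonically(self, toy_run):
        _, history = toy_run
        hv = [h["hypervolume"] for h in history]
        assert all(hv[i + 1] >= hv[i] - 1e-9 for i in range(len(hv) - 1))

    def test_same_seed_reproduces_front_exactly(self, ankle_subject_noiseless):
        dataset, truth, bounds = ankle_subject_noiseless
        cfg = ident.GAConfig(population_size=24, generations=4)
        f1 = ident.run_identification(dataset, truth.activations, bounds,
                                      cfg, seed=9)
        f2 = ident.run_identification(dataset, truth.activations, bounds,
                                      cfg, seed=9)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.vector.values, b.vector.values)
            assert a.C_met == b.C_met and a.C_kin == b.C_kin

    def test_paper_scale_preset_matches_published_settings(self):
        assert ident.PAPER_SCALE.population_size == 1000
        assert ident.PAPER_SCALE.generations == 100
        assert ident.PAPER_SCALE.elite_count == 25
        assert ident.PAPER_SCALE.crossover_fraction == 0.8
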