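"""Dual-objective identification of muscle-tendon morphology.

The morphology vector (per muscle: F_max, a joint length scale for
(l_sl, l_opt), tendon shape factor K_sh, tendon reference strain
lambda_ref; plus the hip ligament's stiffness and engagement angle) is
searched with an elitist NSGA-II-style genetic algorithm that
simultaneously minimizes metabolic cost C_met and kinetic misfit
C_kin = 1 - mean R^2 against the measured joint moments. Candidates are
simulated for two gait cycles with the second scored, and failed
simulations are assigned dominated penalty costs rather than raising.

The returned front is the nondominated subset of every candidate
evaluated during the run (an external archive), which is deterministic
given the seed and guarantees that front quality never regresses across
generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import energetics as en
from . import mtu as mtu_mod
from .datatypes import (Bounds, GaitDataset, MorphologyVector,
                        ParetoSolution, PER_MUSCLE_PARAMS)
from .muscles import MUSCLES

__all__ = [
    "GAConfig", "PAPER_SCALE", "DESK_SCALE",
    "kinetic_cost", "fmae", "build_bounds", "evaluate_candidate",
    "run_identification", "hypervolume_2d",
]

#: tendon material bounds (shape factor, reference strain)
K_SH_BOUNDS = (2.0, 5.0)
LAMBDA_REF_BOUNDS = (0.02, 0.09)
F_MAX_WINDOW = (0.5, 3.0)  # multiples of the reference strength
THETA_HFL_LOWER = -math.pi / 18  # ligament may engage up to 10 deg flexed

#: penalty objectives for candidates whose simulation fails
PENALTY_C_KIN = 2.0
PENALTY_BASAL_FACTOR = 10.0


@dataclass(frozen=True)
class GAConfig:
    """Genetic algorithm settings.

    elite_count is kept for parity with the original MATLAB-style
    configuration; the NSGA-II environmental selection used here is
    already fully elitist, so it is informational only.
    """

    population_size: int = 64
    generations: int = 20
    elite_count: int = 25
    crossover_fraction: float = 0.8
    mutation_sigma: float = 0.02  # fraction of each parameter's range
    sbx_eta: float = 15.0
    #: local least-squares refinement of the best-kinetic-fit corner after
    #: the evolutionary run (0 disables). Starts are mutually distant
    #: low-C_kin archive points; each muscle's force-length-limb mirror is
    #: also tried (the bell curve is symmetric, so operating ranges
    #: reflected about l_opt fit almost equally well and form separate
    #: local basins).
    polish_starts: int = 3
    polish_max_nfev: int = 250


PAPER_SCALE = GAConfig(population_size=1000, generations=100)
DESK_SCALE = GAConfig(population_size=64, generations=20)


# ---------------------------------------------------------------------------
# cost functions

def kinetic_cost(tau_mod: dict[str, np.ndarray],
                 tau_exp: dict[str, np.ndarray]) -> tuple[float, dict[str, float]]:
    """Kinetic misfit C_kin = 1 - mean per-joint R^2.

    R^2 is the ordinary coefficient of determination of the modeled
    moment against the measured one and may be negative for poor fits.
    """
    r2: dict[str, float] = {}
    for j, exp in tau_exp.items():
        exp = np.asarray(exp, dtype=float)
        mod = np.asarray(tau_mod[j], dtype=float)
        ss_tot = float(np.sum((exp - exp.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"zero-variance experimental torque at {j}")
        ss_res = float(np.sum((exp - mod) ** 2))
        r2[j] = 1.0 - ss_res / ss_tot
    c_kin = 1.0 - float(np.mean(list(r2.values())))
    return c_kin, r2


def fmae(tau_mod: np.ndarray, tau_exp: np.ndarray,
         stance_mask: np.ndarray) -> float:
    """Fractional mean absolute error over the stance phase:
    mean |tau_exp - tau_mod| divided by the stance range of tau_exp."""
    tau_mod = np.asarray(tau_mod, dtype=float)[stance_mask]
    tau_exp = np.asarray(tau_exp, dtype=float)[stance_mask]
    rng = float(np.ptp(tau_exp))
    if rng == 0:
        raise ValueError("zero torque range over stance")
    return float(np.mean(np.abs(tau_exp - tau_mod))) / rng


def stance_mask(dataset: GaitDataset) -> np.ndarray:
    """Boolean mask of the stance phase (heel strike to toe-off) on the
    mechanics grid of the dataset's first cycle."""
    t = dataset.time
    hs = dataset.events.heel_strikes[0]
    to = dataset.events.toe_offs[0]
    return (t >= hs) & (t < to)


# ---------------------------------------------------------------------------
# bounds

def build_bounds(dataset: GaitDataset, reference_F_max: dict[str, float],
                 include_ligament: bool = True) -> Bounds:
    """Construct box bounds for the morphology vector from a dataset.

    Strength windows are [0.5, 3.0] times the supplied reference F_max.
    The per-muscle length-scale interval is the set of scales for which a
    rigid-tendon fascicle sweep over the cycle stays inside
    [l_opt(1-w), l_opt(1+w)] (closed form under the constant-width
    pennation model). Tendon material bounds are fixed; the ligament's
    engagement angle may sit up to 10 degrees of flexion and its
    stiffness up to twice the peak hip moment per radian of peak
    extension (enough to supply all of the hip flexion moment alone).
    """
    muscles = tuple(dataset.muscles)
    lower: list[float] = []
    upper: list[float] = []
    meta: dict = {"length_scale_intervals": {}}
    for m in muscles:
        spec = MUSCLES[m]
        L = dataset.mtu_lengths[m]
        L_min, L_max = float(L.min()), float(L.max())
        cos0 = math.cos(spec.theta0)
        s_lo = L_max / (spec.l_sl_ref + (1 + spec.w) * spec.l_opt_ref * cos0)
        s_hi = L_min / (spec.l_sl_ref + (1 - spec.w) * spec.l_opt_ref * cos0)
        if s_lo >= s_hi:
            raise ValueError(
                f"{m}: no feasible length-scale interval "
                f"(sweep [{L_min:.4f}, {L_max:.4f}] m too wide for width "
                f"w={spec.w})")
        meta["length_scale_intervals"][m] = (s_lo, s_hi)
        ref = reference_F_max[m]
        lower += [F_MAX_WINDOW[0] * ref, s_lo, K_SH_BOUNDS[0], LAMBDA_REF_BOUNDS[0]]
        upper += [F_MAX_WINDOW[1] * ref, s_hi, K_SH_BOUNDS[1], LAMBDA_REF_BOUNDS[1]]
    if include_ligament:
        theta_hip = dataset.joint_angles["hip"]
        tau_hip = dataset.joint_moments["hip"]
        min_ext = abs(float(theta_hip.min()))
        if min_ext == 0:
            raise ValueError("hip never extends; ligament bounds undefined")
        k_hi = 2.0 * float(np.max(tau_hip)) / min_ext
        if k_hi <= 0:  # partial dataset with zero moments: nominal ceiling
            k_hi = 2.0 * dataset.scalars.body_mass * 9.81 * 0.1 / min_ext
        lower += [0.0, THETA_HFL_LOWER]
        upper += [k_hi, min_ext]
        meta["K_HFL_upper"] = k_hi
    return Bounds(muscles=muscles, lower=np.array(lower),
                  upper=np.array(upper), has_ligament=include_ligament,
                  meta=meta)


# ---------------------------------------------------------------------------
# candidate evaluation

def evaluate_candidate(vector: MorphologyVector, dataset: GaitDataset,
                       activations: dict[str, np.ndarray],
                       drives: dict[str, np.ndarray] | None = None,
                       method: str = "fast") -> tuple[float, float, dict]:
    """Simulate one morphology on a dataset and score both objectives.

    Returns (C_met [J per cycle], C_kin, diagnostics). Simulation
    failures yield dominated penalty costs with a diagnostic flag instead
    of raising, so optimizer loops never abort.
    """
    from .synthetic import params_from_vector

    scal = dataset.scalars
    T = dataset.time.size * dataset.dt
    try:
        params, hfl = params_from_vector(vector)
        traces, tau_mod = mtu_mod.simulate_leg(dataset, activations, params,
                                               hfl=hfl, method=method)
        c_kin, r2 = kinetic_cost(tau_mod, dataset.joint_moments)
        u = drives if drives is not None else activations
        report = en.energetics_report(traces, u, activations, params, scal,
                                      events=None)
        fractions = {m: 2.0 * report.muscle_energy[m] / report.C_met
                     for m in report.muscle_energy}
        diag = {"r2": r2, "mean_R2": 1.0 - c_kin, "mcot": report.mcot,
                "fractions": fractions, "failed": False,
                "clamped": {m: tr.clamped for m, tr in traces.items()}}
        return report.C_met, c_kin, diag
    except (mtu_mod.SimulationError, FloatingPointError, ValueError) as err:
        basal_only = scal.body_mass * scal.basal_rate * T
        return (PENALTY_BASAL_FACTOR * basal_only, PENALTY_C_KIN,
                {"failed": True, "error": str(err), "r2": {},
                 "mean_R2": 1.0 - PENALTY_C_KIN, "mcot": float("nan"),
                 "fractions": {}})


# ---------------------------------------------------------------------------
# local refinement of the best-kinetic-fit corner

def _kinetic_residuals(x: np.ndarray, bounds: Bounds, dataset: GaitDataset,
                       activations: dict[str, np.ndarray]) -> np.ndarray:
    """Standardized joint-moment residual vector for least-squares polish."""
    from .synthetic import params_from_vector

    vec = MorphologyVector(muscles=bounds.muscles, values=x,
                           has_ligament=bounds.has_ligament)
    n_tot = sum(v.size for v in dataset.joint_moments.values())
    try:
        params, hfl = params_from_vector(vec)
        _, tau = mtu_mod.simulate_leg(dataset, activations, params, hfl=hfl)
    except (mtu_mod.SimulationError, ValueError):
        return np.full(n_tot, 1e3)
    return np.concatenate([(tau[j] - exp) / np.std(exp)
                           for j, exp in dataset.joint_moments.items()])


def _polish_front(dataset: GaitDataset, activations: dict[str, np.ndarray],
                  bounds: Bounds, front_x: list[np.ndarray],
                  ga_config: GAConfig) -> list[np.ndarray]:
    """Least-squares refinement of low-C_kin front candidates.

    Polishes up to polish_starts mutually distant starts, then probes each
    muscle's force-length-limb mirror of the best polished point (reflected
    operating ranges fit almost equally well and sit in separate basins, so
    the local solver alone cannot cross between them).
    """
    import math

    from scipy.optimize import least_squares

    from .muscles import MUSCLES as MUSCLE_TABLE
    from .synthetic import params_from_vector

    span = bounds.upper - bounds.lower

    def refine(x0: np.ndarray) -> tuple[np.ndarray, float]:
        res = least_squares(
            _kinetic_residuals, np.clip(x0, bounds.lower, bounds.upper),
            bounds=(bounds.lower, bounds.upper), diff_step=1e-5,
            max_nfev=ga_config.polish_max_nfev,
            args=(bounds, dataset, activations))
        return res.x, float(np.sum(res.fun ** 2))

    starts: list[np.ndarray] = []
    for x in front_x:
        if all(np.max(np.abs((x - y) / span)) > 0.08 for y in starts):
            starts.append(x)
        if len(starts) >= ga_config.polish_starts:
            break
    polished: list[np.ndarray] = []
    best_x, best_cost = None, np.inf
    for x0 in starts:
        x, cost = refine(x0)
        polished.append(x)
        if cost < best_cost:
            best_x, best_cost = x, cost

    if best_x is not None:
        params, _ = params_from_vector(MorphologyVector(
            muscles=bounds.muscles, values=best_x,
            has_ligament=bounds.has_ligament))
        for i, m in enumerate(bounds.muscles):
            try:
                tr = mtu_mod.simulate_mtu(dataset.time,
                                          dataset.mtu_lengths[m],
                                          activations[m], params[m])
            except mtu_mod.SimulationError:
                continue
            mu = float(np.mean(tr.l_CE)) / params[m].l_opt
            spec = MUSCLE_TABLE[m]
            denom = (spec.l_sl_ref + (2.0 - mu) * spec.l_opt_ref
                     * math.cos(spec.theta0))
            s_mirror = float(np.mean(dataset.mtu_lengths[m])) / denom
            lo_s, hi_s = bounds.lower[4 * i + 1], bounds.upper[4 * i + 1]
            if not (lo_s <= s_mirror <= hi_s):
                continue
            if abs(s_mirror - best_x[4 * i + 1]) < 0.02 * (hi_s - lo_s):
                continue  # same basin
            x0 = best_x.copy()
            x0[4 * i + 1] = s_mirror
            x, cost = refine(x0)
            polished.append(x)
            if cost < best_cost:
                best_x, best_cost = x, cost
    return polished


# ---------------------------------------------------------------------------
# NSGA-II machinery

def _nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast nondominated sort of objective rows (minimization)."""
    n = F.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dom = np.zeros(n, dtype=int)
    for i in range(n):
        d = np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1)
        dominators = np.nonzero(d)[0]
        n_dom[i] = dominators.size
        for j in dominators:
            dominated_by[j].append(i)
    fronts: list[np.ndarray] = []
    current = np.nonzero(n_dom == 0)[0]
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dom[j] -= 1
                if n_dom[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k])
        span = F[order[-1], k] - F[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return dist


def _sbx(p1: np.ndarray, p2: np.ndarray, lo: np.ndarray, hi: np.ndarray,
         eta: float, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (0.5 / (1 - u)) ** (1 / (eta + 1)))
    child = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    return np.clip(child, lo, hi)


def _mutate(p: np.ndarray, lo: np.ndarray, hi: np.ndarray, sigma: float,
            rng: np.random.Generator) -> np.ndarray:
    """Gaussian mutation, per-parameter SD = sigma * range, resampled into
    bounds (feasibility-preserving)."""
    out = p.copy()
    span = hi - lo
    for _ in range(20):
        cand = p + rng.normal(0.0, sigma * span)
        inside = (cand >= lo) & (cand <= hi)
        out = np.where(inside, cand, out)
        if inside.all():
            break
        p = out
    return np.clip(out, lo, hi)


def hypervolume_2d(F: np.ndarray, ref: tuple[float, float]) -> float:
    """Dominated hypervolume of a 2-objective front w.r.t. a reference point."""
    pts = F[np.all(F <= np.asarray(ref), axis=1)]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0])]
    # sweep left to right, accumulating rectangles of successive
    # nondominated points
    nd = []
    best_y = np.inf
    for x, y in pts:
        if y < best_y:
            nd.append((x, y))
            best_y = y
    hv = 0.0
    prev_y = ref[1]
    for x, y in nd:
        hv += (ref[0] - x) * (prev_y - y)
        prev_y = y
    return float(hv)


def _tournament(rank: np.ndarray, crowd: np.ndarray,
                rng: np.random.Generator) -> int:
    i, j = rng.integers(rank.size, size=2)
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    return int(i if crowd[i] >= crowd[j] else j)


def run_identification(dataset: GaitDataset,
                       activations: dict[str, np.ndarray],
                       bounds: Bounds, ga_config: GAConfig = DESK_SCALE,
                       seed: int = 0,
                       drives: dict[str, np.ndarray] | None = None,
                       return_history: bool = False):
    """NSGA-II-style dual-objective search over the morphology box.

    The initial population is uniform over the full bounded space (no
    seeding); selection is binary tournament on (rank, crowding);
    offspring are SBX crossover children (crossover_fraction of the
    population) or Gaussian-mutated parents (the remainder); survivors
    are chosen by elitist nondominated sorting with crowding truncation.
    Returns the nondominated archive of all evaluations as a list of
    ParetoSolution sorted by ascending C_kin; with return_history=True a
    per-generation statistics list is appended to the return value.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    n_var = bounds.size
    pop = ga_config.population_size

    def make_vec(x: np.ndarray) -> MorphologyVector:
        return MorphologyVector(muscles=bounds.muscles, values=x,
                                has_ligament=bounds.has_ligament)

    def evaluate(x: np.ndarray):
        c_met, c_kin, diag = evaluate_candidate(make_vec(x), dataset,
                                                activations, drives=drives)
        return np.array([c_met, c_kin]), diag

    X = rng.uniform(lo, hi, size=(pop, n_var))
    F = np.empty((pop, 2))
    diags: list[dict] = [None] * pop  # type: ignore[list-item]
    for i in range(pop):
        F[i], diags[i] = evaluate(X[i])

    # external archive of every nondominated candidate seen so far
    arch_X: list[np.ndarray] = []
    arch_F: list[np.ndarray] = []
    arch_D: list[dict] = []

    def archive_update(X_new, F_new, D_new):
        for x, f, d in zip(X_new, F_new, D_new):
            if d.get("failed"):
                continue
            arch_X.append(x.copy())
            arch_F.append(f.copy())
            arch_D.append(d)
        if not arch_F:
            return
        Fa = np.vstack(arch_F)
        keep = _nondominated_sort(Fa)[0]
        for lst in (arch_X, arch_F, arch_D):
            lst[:] = [lst[i] for i in keep]

    archive_update(X, F, diags)
    ref_point = (float(F[:, 0].max()) * 1.1 + 1.0, PENALTY_C_KIN + 0.1)
    history: list[dict] = []

    for gen in range(ga_config.generations):
        fronts = _nondominated_sort(F)
        rank = np.empty(pop, dtype=int)
        crowd = np.empty(pop)
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding(F[fr])

        n_cross = int(round(ga_config.crossover_fraction * pop))
        children = np.empty((pop, n_var))
        for c in range(pop):
            p1 = X[_tournament(rank, crowd, rng)]
            if c < n_cross:
                p2 = X[_tournament(rank, crowd, rng)]
                child = _sbx(p1, p2, lo, hi, ga_config.sbx_eta, rng)
                # light per-gene refinement keeps exploitation sharp once
                # the front has localized
                touch = rng.random(n_var) < 1.0 / n_var
                if touch.any():
                    noise = rng.normal(0.0, ga_config.mutation_sigma
                                       * (hi - lo))
                    child = np.where(touch, np.clip(child + noise, lo, hi),
                                     child)
                children[c] = child
            else:
                children[c] = _mutate(p1, lo, hi, ga_config.mutation_sigma, rng)

        F_child = np.empty((pop, 2))
        diags_child: list[dict] = [None] * pop  # type: ignore[list-item]
        for i in range(pop):
            F_child[i], diags_child[i] = evaluate(children[i])
        archive_update(children, F_child, diags_child)

        # elitist environmental selection on parents + offspring
        X_all = np.vstack([X, children])
        F_all = np.vstack([F, F_child])
        D_all = diags + diags_child
        sel: list[int] = []
        for fr in _nondominated_sort(F_all):
            if len(sel) + fr.size <= pop:
                sel.extend(fr.tolist())
            else:
                cd = _crowding(F_all[fr])
                order = np.argsort(-cd)
                sel.extend(fr[order][:pop - len(sel)].tolist())
                break
        sel_arr = np.array(sel[:pop])
        X, F = X_all[sel_arr], F_all[sel_arr]
        diags = [D_all[i] for i in sel_arr]

        if return_history:
            Fa = np.vstack(arch_F)
            history.append({
                "generation": gen,
                "front_size": len(arch_F),
                "hypervolume": hypervolume_2d(Fa, ref_point),
                "best_c_kin": float(Fa[:, 1].min()),
                "best_c_met": float(Fa[:, 0].min()),
            })

    if ga_config.polish_starts > 0 and arch_F:
        order = np.argsort([f[1] for f in arch_F])
        front_x = [arch_X[i] for i in order]
        for x in _polish_front(dataset, activations, bounds, front_x,
                               ga_config):
            f, d = evaluate(x)
            archive_update([x], [np.asarray(f)], [d])

    solutions = []
    for x, f, d in zip(arch_X, arch_F, arch_D):
        solutions.append(ParetoSolution(
            vector=make_vec(x), C_met=float(f[0]),
            mcot=float(d.get("mcot", float("nan"))), C_kin=float(f[1]),
            mean_R2=float(d.get("mean_R2", 1.0 - f[1])),
            per_joint_R2=d.get("r2", {}),
            muscle_fractions=d.get("fractions", {}), diagnostics=d))
    solutions.sort(key=lambda s: s.C_kin)
    if return_history:
        return solutions, history
    return solutions
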