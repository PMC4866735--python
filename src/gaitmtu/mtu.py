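"""Muscle-tendon unit simulation over prescribed kinematics.

The contraction dynamics have a single state per muscle, the fascicle
length l_CE. At every instant the series force balance

    F_SE(lam) = (F_CE(a, l_CE, v_CE) + F_PE(l_CE) + c v_CE) cos(theta)

is solved for v_CE in closed form (the damped-equilibrium formulation: a
light damper c in parallel with the contractile element keeps the
velocity defined at any activation, including zero), and l_CE is
integrated forward. Simulations run for two gait cycles with the second
returned, which flushes the initial transient (the contraction time
constant is tens of milliseconds against a cycle of about a second).

`solve_ce_velocity` additionally exposes the classical undamped balance
(exact analytic force-velocity inversion with an activation floor), which
is the form used for isolated-state analysis and the bisection oracle.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from . import hill
from .datatypes import GaitDataset, HFLParams, MTUParams, MTUTrace

__all__ = [
    "tendon_force", "tendon_strain", "pennation_angle", "ce_force",
    "solve_ce_velocity", "simulate_mtu", "hfl_torque", "joint_moments",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the contraction dynamics cannot be advanced."""


def tendon_force(lam, params: MTUParams):
    """Series-elastic (tendon) force at strain lam.

    Exponential force-strain law: zero for slack tendon (lam <= 0),
    F_max exactly at the reference strain lam_ref, strictly increasing
    in between with toe-region shape set by K_sh.
    """
    lam = np.asarray(lam, dtype=float)
    denom = math.expm1(params.K_sh)
    out = np.where(
        lam > 0.0,
        params.F_max * np.expm1(params.K_sh * np.clip(lam, 0.0, None) / params.lambda_ref) / denom,
        0.0,
    )
    return out if out.ndim else float(out)


def tendon_strain(l_se, params: MTUParams):
    """Strain of the tendon beyond its slack length."""
    return (np.asarray(l_se, dtype=float) - params.l_sl) / params.l_sl


def pennation_angle(l_ce, params: MTUParams, warn: bool = True):
    """Pennation angle under the constant-muscle-width assumption.

    theta = arcsin(l_opt sin(theta0) / l_CE). Below the geometric minimum
    fascicle length the angle is clamped just under 90 degrees and a
    warning is emitted (the state is flagged rather than fatal).
    """
    l_ce = np.asarray(l_ce, dtype=float)
    s = params.l_opt * math.sin(params.theta0) / l_ce
    if np.any(s > 1.0) and warn:
        warnings.warn(f"{params.name}: fascicle below geometric minimum length; "
                      "pennation clamped", RuntimeWarning, stacklevel=2)
    # exactly at the minimum the fibers are perpendicular (90 deg); only
    # below it is the angle clamped just short of 90 deg
    out = np.arcsin(np.where(s > 1.0, hill.PENNATION_SIN_MAX, s))
    return out if out.ndim else float(out)


def ce_force(a, l_ce, v_ce, params: MTUParams):
    """Contractile and parallel-elastic forces at the given state.

    F_CE = a F_max f_l(l_CE) f_v(v_CE); F_PE engages only above l_opt.
    """
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    fl = hill.force_length(l_ce, params.l_opt, params.w)
    fv = hill.force_velocity(v_ce, params.v_max_abs)
    f_ce = a * params.F_max * fl * fv
    f_pe = hill.parallel_force(l_ce, params.l_opt, params.w, params.F_max)
    if np.ndim(f_ce) == 0:
        return float(f_ce), float(f_pe)
    return f_ce, f_pe


def solve_ce_velocity(a: float, l_ce: float, l_mtc: float,
                      params: MTUParams) -> float:
    """Fascicle velocity satisfying the series force balance.

    The force-velocity relation is inverted analytically on the concentric
    and eccentric branches. Raises SimulationError when no velocity in
    [-v_max, +v_max] balances the tendon force (e.g. a nearly inactive
    muscle pulled beyond its eccentric force ceiling).
    """
    theta = pennation_angle(l_ce, params, warn=False)
    cosT = math.cos(theta)
    lam = (l_mtc - l_ce * cosT - params.l_sl) / params.l_sl
    Fse = tendon_force(lam, params)
    Fpe = hill.parallel_force(l_ce, params.l_opt, params.w, params.F_max)
    fl = hill.force_length(l_ce, params.l_opt, params.w)
    a_eff = max(float(a), hill.ACTIVATION_FLOOR)
    denom = a_eff * params.F_max * fl
    f_req = (Fse / cosT - Fpe) / denom
    v_max = params.v_max_abs
    f_lo = hill.force_velocity(-v_max, v_max)
    f_hi = hill.force_velocity(v_max, v_max)
    if not (f_lo <= f_req <= f_hi):
        raise SimulationError(
            f"{params.name}: no fascicle velocity in [-v_max, v_max] balances "
            f"required force multiplier {f_req:.3f} "
            f"(l_CE={l_ce:.4f} m, l_MTC={l_mtc:.4f} m, a={a:.3f})")
    v = hill.force_velocity_inverse(f_req, v_max)
    # bisection fallback in case the analytic branches ever disagree
    resid = hill.force_velocity(v, v_max) - f_req
    if abs(resid) * denom > 1e-8 * max(params.F_max, 1.0):
        lo, hi = -v_max, v_max
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if hill.force_velocity(mid, v_max) < f_req:
                lo = mid
            else:
                hi = mid
        v = 0.5 * (lo + hi)
    return float(v)


def _periodic_fine_grid(time: np.ndarray, series: np.ndarray, n_sub: int,
                        n_cycles: int = 2) -> np.ndarray:
    """Resample one periodic cycle onto a fine grid spanning n_cycles.

    The input grid covers [0, T) with the next cycle wrapping to sample 0.
    Output has n_cycles * n * n_sub + 1 points (closing sample included).
    """
    n = time.size
    dt = time[1] - time[0]
    T = n * dt
    t_ext = np.concatenate([time + k * T for k in range(n_cycles + 1)])
    y_ext = np.tile(series, n_cycles + 1)
    t_fine = np.arange(n_cycles * n * n_sub + 1) * (dt / n_sub)
    return np.interp(t_fine, t_ext, y_ext)


def simulate_mtu(time: np.ndarray, l_mtc: np.ndarray, a: np.ndarray,
                 params: MTUParams, n_sub: int | None = None,
                 method: str = "fast") -> MTUTrace:
    """Simulate one MTU over two periodic gait cycles; return the second.

    Parameters
    ----------
    time, l_mtc, a : one gait cycle on a uniform grid covering [0, T)
        (the sample at T wraps around to index 0).
    params : muscle morphology.
    n_sub : substeps per mechanics-grid interval for the fixed-step path;
        default 8 (1 ms at 125 Hz), automatically increased for very stiff
        (small lambda_ref) tendons.
    method : "fast" (compiled fixed-step Heun) or "lsoda" (SciPy
        variable-step stiff solver); the two agree to solver tolerance and
        the fast path is used inside optimization loops.

    The returned trace reconstructs v_CE from the exact series force
    balance at every output sample, so the force-balance residual of the
    trace is zero to rounding. `trace.clamped` counts integrator steps at
    which the balance demanded speeds beyond v_max (velocity clamped).
    """
    time = np.asarray(time, dtype=float)
    l_mtc = np.asarray(l_mtc, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (time.shape == l_mtc.shape == a.shape):
        raise ValueError("time, l_mtc and a must share one grid")
    if np.any(~np.isfinite(a)) or np.any((a < 0) | (a > 1)):
        raise ValueError("activation must be finite and lie in [0, 1]")
    if np.any(~np.isfinite(l_mtc)):
        raise ValueError("non-finite MTU length input")
    n = time.size
    dt = float(time[1] - time[0])
    if n_sub is None:
        n_sub = 8
        if params.lambda_ref < 0.02:  # very stiff tendon: refine step
            n_sub = int(8 * math.ceil(0.02 / params.lambda_ref))
    p = params

    if method == "fast":
        lm_fine = _periodic_fine_grid(time, l_mtc, n_sub)
        a_fine = _periodic_fine_grid(time, a, n_sub)
        l_out, clamped = hill._integrate(
            lm_fine, a_fine, dt / n_sub, p.F_max, p.l_opt, p.l_sl, p.K_sh,
            p.lambda_ref, math.sin(p.theta0), p.w, p.v_max_abs,
            n_sub, n, n * n_sub)
    elif method == "lsoda":
        T = n * dt
        t_ext = np.concatenate([time, time + T, [2 * T]])
        lm_ext = np.concatenate([l_mtc, l_mtc, [l_mtc[0]]])
        a_ext = np.concatenate([a, a, [a[0]]])
        sin0 = math.sin(p.theta0)

        def rhs(t, y):
            lm = np.interp(t, t_ext, lm_ext)
            at = np.interp(t, t_ext, a_ext)
            return [hill._ce_velocity(y[0], lm, at, p.F_max, p.l_opt, p.l_sl,
                                      p.K_sh, p.lambda_ref, sin0, p.w,
                                      p.v_max_abs)]

        l0 = hill._static_equilibrium(l_mtc[0], a[0], p.F_max, p.l_opt,
                                      p.l_sl, p.K_sh, p.lambda_ref, sin0, p.w)
        sol = solve_ivp(rhs, (0.0, 2 * T), [l0], method="LSODA",
                        t_eval=time + T, rtol=1e-7, atol=1e-9 * p.l_opt,
                        max_step=dt)
        if not sol.success:
            raise SimulationError(f"{p.name}: LSODA failed: {sol.message}")
        l_out, clamped = sol.y[0], 0
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.any(~np.isfinite(l_out)):
        bad = int(np.nonzero(~np.isfinite(l_out))[0][0])
        raise SimulationError(f"{p.name}: non-finite fascicle length at "
                              f"output sample {bad}")

    # reconstruct the full trace from the state, enforcing the damped
    # force balance: F_SE = (F_CE + F_PE + c v_CE) cos(theta)
    sinT = np.clip(p.l_opt * math.sin(p.theta0) / l_out, 0.0,
                   hill.PENNATION_SIN_MAX)
    cosT = np.sqrt(1.0 - sinT ** 2)
    lam = (l_mtc - l_out * cosT - p.l_sl) / p.l_sl
    F_se = tendon_force(lam, p)
    F_pe = hill.parallel_force(l_out, p.l_opt, p.w, p.F_max)
    sin0 = math.sin(p.theta0)
    v = np.array([hill._ce_velocity(l_out[i], l_mtc[i], a[i], p.F_max,
                                    p.l_opt, p.l_sl, p.K_sh, p.lambda_ref,
                                    sin0, p.w, p.v_max_abs)
                  for i in range(n)])
    c_damp = hill.CE_DAMPING * p.F_max / p.v_max_abs
    F_ce = F_se / cosT - F_pe - c_damp * v
    return MTUTrace(name=p.name, time=time.copy(), l_CE=l_out, v_CE=v,
                    theta=np.arcsin(sinT), F_CE=F_ce, F_PE=F_pe, F_SE=F_se,
                    lam=lam, clamped=int(clamped))


def hfl_torque(theta_hip, params: HFLParams):
    """Hip flexor ligament torque (flexion positive).

    A linear rotary spring that engages only when the hip extends past the
    engagement angle theta0_HFL: tau = -K (theta - theta0) for
    theta < theta0, else 0. Engaged torque is a pure flexion moment.
    """
    th = np.asarray(theta_hip, dtype=float)
    out = np.where(th < params.theta0_HFL,
                   -params.K_HFL * (th - params.theta0_HFL), 0.0)
    return out if out.ndim else float(out)


def joint_moments(traces: dict[str, MTUTrace],
                  moment_arms: dict[str, dict[str, np.ndarray]],
                  hfl: HFLParams | None = None,
                  theta_hip: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Assemble modeled joint moments from MTU forces and moment arms.

    tau_j(t) = sum_i F_MTC,i(t) r_ij(t), with biarticular muscles
    contributing at every joint they span; the passive hip flexor ligament
    adds its torque at the hip when provided.
    """
    joints: dict[str, np.ndarray] = {}
    for m, tr in traces.items():
        if m not in moment_arms:
            raise KeyError(f"no moment-arm channels for muscle {m!r}")
        for j, r in moment_arms[m].items():
            r = np.asarray(r, dtype=float)
            contrib = tr.F_MTC * r
            joints[j] = joints.get(j, 0.0) + contrib
    if hfl is not None:
        if theta_hip is None:
            raise ValueError("theta_hip required when the ligament is included")
        joints["hip"] = joints.get("hip", 0.0) + hfl_torque(theta_hip, hfl)
    return joints


def simulate_leg(dataset: GaitDataset, activations: dict[str, np.ndarray],
                 params: dict[str, MTUParams], hfl: HFLParams | None = None,
                 method: str = "fast") -> tuple[dict[str, MTUTrace], dict[str, np.ndarray]]:
    """Simulate every muscle of a dataset and assemble joint moments."""
    traces = {}
    for m, p in params.items():
        traces[m] = simulate_mtu(dataset.time, dataset.mtu_lengths[m],
                                 activations[m], p, method=method)
    theta_hip = dataset.joint_angles.get("hip")
    tau = joint_moments(traces, {m: dataset.moment_arms[m] for m in params},
                        hfl=hfl, theta_hip=theta_hip)
    return traces, tau
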