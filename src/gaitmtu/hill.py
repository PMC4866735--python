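"""Hill-type muscle and tendon constitutive relations, and the compiled
fixed-step contraction-dynamics kernel.

Conventions
-----------
* Contractile-element velocity v_CE is positive when the fascicle lengthens
  (eccentric motion) and negative when it shortens.
* The force-velocity multiplier f_v is expressed in terms of the normalized
  speed v/v_max and is therefore evaluated with absolute velocities against
  the muscle's absolute v_max (v_max [l_opt/s] * l_opt).

Curve set
---------
* Active force-length: bell  f_l = exp(ln(0.05) * |(l-l_opt)/(l_opt*w)|^3),
  i.e. the multiplier decays to 0.05 at the edges of the operating width w.
* Force-velocity: concentric Hill hyperbola with curvature K (default 5),
  f_v = (v_max - |v|)/(v_max + K|v|); eccentric branch saturating at N
  (default 1.5) via f_v = N - (N-1)(v_max + v)/(7.56 K v + v_max).
* Parallel element: quadratic above l_opt, reaching F_max at l_opt(1+w).
* Series (tendon) element: exponential force-strain,
  F = F_max (exp(K_sh * lam/lam_ref) - 1)/(exp(K_sh) - 1), zero when slack;
  by construction F(lam_ref) = F_max for any shape factor K_sh.

All constants are plain module-level names so that alternative calibrations
can be injected per muscle through MTUParams.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "FV_K", "FV_N", "FL_LN", "PENNATION_SIN_MAX", "ACTIVATION_FLOOR",
    "force_length", "force_velocity", "force_velocity_inverse",
    "parallel_force", "tendon_force_scalar", "optimal_power_velocity",
]

FV_K = 5.0          # concentric force-velocity curvature
FV_N = 1.5          # eccentric force plateau, units of F_max
FV_ECC_SLOPE = 7.56  # eccentric branch shape constant (times K)
FL_LN = math.log(0.05)  # force-length bell floor at the width edge
PENNATION_SIN_MAX = math.sin(math.radians(89.9))  # pennation clamp guard
ACTIVATION_FLOOR = 5e-3  # activation floor of the undamped balance solver
CE_DAMPING = 0.1  # parallel CE damping, units of F_max per v_max
ECC_VEL_CAP = 2.0  # lengthening speed cap, units of v_max (integration guard)


def optimal_power_velocity(K: float = FV_K) -> float:
    """Normalized shortening speed (fraction of v_max) that maximizes CE
    power a*F_max*f_v(v)*|v| for the concentric hyperbola with curvature K.

    Closed form: maximizing s*(1-s)/(1+K*s) over s = |v|/v_max gives
    s* = (sqrt(1+K) - 1)/K.
    """
    return (math.sqrt(1.0 + K) - 1.0) / K


# ---------------------------------------------------------------------------
# scalar kernels (numba). Python-facing array wrappers follow below.

@njit(cache=True, fastmath=False)
def _fl(l_ce: float, l_opt: float, w: float) -> float:
    x = abs((l_ce - l_opt) / (l_opt * w))
    return math.exp(FL_LN * x * x * x)


@njit(cache=True, fastmath=False)
def _fpe(l_ce: float, l_opt: float, w: float, F_max: float) -> float:
    if l_ce <= l_opt:
        return 0.0
    x = (l_ce - l_opt) / (l_opt * w)
    return F_max * x * x


@njit(cache=True, fastmath=False)
def _fse(lam: float, F_max: float, K_sh: float, lam_ref: float) -> float:
    if lam <= 0.0:
        return 0.0
    return F_max * (math.exp(K_sh * lam / lam_ref) - 1.0) / (math.exp(K_sh) - 1.0)


@njit(cache=True, fastmath=False)
def _fv(v: float, v_max: float, K: float, N: float) -> float:
    if v <= 0.0:  # shortening
        s = -v
        if s >= v_max:
            return 0.0
        return (v_max - s) / (v_max + K * s)
    # lengthening
    return N - (N - 1.0) * (v_max + v) / (FV_ECC_SLOPE * K * v + v_max)


@njit(cache=True, fastmath=False)
def _fv_inv(f: float, v_max: float, K: float, N: float) -> float:
    """Velocity at which f_v equals f, clamped to [-v_max, +v_max]."""
    if f <= 0.0:
        return -v_max
    if f < 1.0:
        return -v_max * (1.0 - f) / (1.0 + K * f)
    # eccentric cap: fastest representable lengthening is +v_max
    f_cap = N - (N - 1.0) * 2.0 / (FV_ECC_SLOPE * K + 1.0)
    if f >= f_cap:
        return v_max
    return v_max * (f - 1.0) / (FV_ECC_SLOPE * K * (N - f) - (N - 1.0))


@njit(cache=True, fastmath=False)
def _pennation_sin(l_ce: float, l_opt: float, sin0: float) -> float:
    if sin0 == 0.0:
        return 0.0
    s = l_opt * sin0 / l_ce
    if s > PENNATION_SIN_MAX:
        return PENNATION_SIN_MAX
    return s


@njit(cache=True, fastmath=False)
def _ce_velocity(l_ce: float, l_mtc: float, a: float,
                 F_max: float, l_opt: float, l_sl: float,
                 K_sh: float, lam_ref: float, sin0: float, w: float,
                 v_max_abs: float) -> float:
    """Fascicle velocity from the damped series force balance.

    Solves  F_SE(lam) / cos(theta) = a F_max f_l f_v(v) + F_PE + c v
    with the light parallel damper c = CE_DAMPING * F_max / v_max (the
    damped-equilibrium formulation), which keeps the velocity well defined
    at any activation, including zero, and for tendon loads beyond the
    eccentric force plateau. Each force-velocity branch yields a quadratic
    in v with a unique admissible root; the result is clamped to
    [-v_max, ECC_VEL_CAP * v_max].
    """
    sinT = _pennation_sin(l_ce, l_opt, sin0)
    cosT = math.sqrt(1.0 - sinT * sinT)
    lam = (l_mtc - l_ce * cosT - l_sl) / l_sl
    Fse = _fse(lam, F_max, K_sh, lam_ref)
    Fpe = _fpe(l_ce, l_opt, w, F_max)
    G = Fse / cosT - Fpe  # force the CE + damper must supply
    Ac = a * F_max * _fl(l_ce, l_opt, w)
    c = CE_DAMPING * F_max / v_max_abs
    if G < Ac:  # shortening: v = -s, s in (0, v_max]
        b = Ac + c * v_max_abs + G * FV_K
        disc = b * b + 4.0 * c * FV_K * v_max_abs * (Ac - G)
        s = (-b + math.sqrt(disc)) / (2.0 * c * FV_K)
        if s > v_max_abs:
            s = v_max_abs
        return -s
    # lengthening (or isometric when G == Ac)
    E = FV_ECC_SLOPE * FV_K
    a2 = E * c
    a1 = Ac * (E * FV_N - (FV_N - 1.0)) + c * v_max_abs - E * G
    a0 = v_max_abs * (Ac - G)  # <= 0
    disc = a1 * a1 - 4.0 * a2 * a0
    v = (-a1 + math.sqrt(disc)) / (2.0 * a2)
    cap = ECC_VEL_CAP * v_max_abs
    if v > cap:
        v = cap
    return v


@njit(cache=True, fastmath=False)
def _static_equilibrium(l_mtc: float, a: float,
                        F_max: float, l_opt: float, l_sl: float,
                        K_sh: float, lam_ref: float, sin0: float,
                        w: float) -> float:
    """Quasi-static fascicle length: tendon force equals muscle force at
    zero velocity. Falls back to the PE rest length when the tendon is slack.
    """
    # slack tendon at the PE rest length: the fascicle has nowhere better
    # to sit than l_opt (every shorter length is force-free too)
    cosT0 = math.sqrt(1.0 - sin0 * sin0)
    if l_mtc - l_opt * cosT0 <= l_sl:
        return l_opt

    lo = max(0.30 * l_opt, l_opt * sin0 * 1.001 + 1e-9)
    hi = 2.2 * l_opt

    def g(l_ce: float) -> float:
        sinT = _pennation_sin(l_ce, l_opt, sin0)
        cosT = math.sqrt(1.0 - sinT * sinT)
        lam = (l_mtc - l_ce * cosT - l_sl) / l_sl
        Fse = _fse(lam, F_max, K_sh, lam_ref)
        Fm = (a * F_max * _fl(l_ce, l_opt, w) + _fpe(l_ce, l_opt, w, F_max))
        return Fse - Fm * cosT

    n = 128
    prev_l = lo
    prev_g = g(lo)
    best_l = lo
    best_abs = abs(prev_g)
    for i in range(1, n + 1):
        l = lo + (hi - lo) * i / n
        gi = g(l)
        if abs(gi) < best_abs:
            best_abs = abs(gi)
            best_l = l
        if prev_g == 0.0:
            return prev_l
        if prev_g * gi < 0.0:
            a_l, b_l = prev_l, l
            for _ in range(60):
                m = 0.5 * (a_l + b_l)
                gm = g(m)
                if prev_g * gm <= 0.0:
                    b_l = m
                else:
                    a_l = m
                    prev_g = gm
            return 0.5 * (a_l + b_l)
        prev_l, prev_g = l, gi
    # no sign change (taut tendon but no crossing in range): nearest balance
    return best_l


@njit(cache=True, fastmath=False)
def _integrate(l_mtc_fine: np.ndarray, a_fine: np.ndarray, dt: float,
               F_max: float, l_opt: float, l_sl: float,
               K_sh: float, lam_ref: float, sin0: float, w: float,
               v_max_abs: float, n_sub: int, n_out: int, out_start: int):
    """Heun (RK2) integration of dl_CE/dt = v_CE over a fine grid.

    Returns fascicle length at the n_out coarse-grid samples beginning at
    fine index out_start (stride n_sub), plus a velocity-clamp counter.
    """
    l = _static_equilibrium(l_mtc_fine[0], a_fine[0], F_max, l_opt, l_sl,
                            K_sh, lam_ref, sin0, w)
    out = np.empty(n_out)
    clamped = 0
    floor = max(0.05 * l_opt, l_opt * sin0 + 1e-9)
    k_out = 0
    n_fine = l_mtc_fine.shape[0]
    for i in range(n_fine):
        if i >= out_start and (i - out_start) % n_sub == 0 and k_out < n_out:
            out[k_out] = l
            k_out += 1
        if i == n_fine - 1:
            break
        v1 = _ce_velocity(l, l_mtc_fine[i], a_fine[i], F_max, l_opt, l_sl,
                          K_sh, lam_ref, sin0, w, v_max_abs)
        lp = l + dt * v1
        if lp < floor:
            lp = floor
        v2 = _ce_velocity(lp, l_mtc_fine[i + 1], a_fine[i + 1], F_max, l_opt,
                          l_sl, K_sh, lam_ref, sin0, w, v_max_abs)
        cap = ECC_VEL_CAP * v_max_abs
        if v1 <= -v_max_abs or v1 >= cap or v2 <= -v_max_abs or v2 >= cap:
            clamped += 1
        l = l + 0.5 * dt * (v1 + v2)
        if l < floor:
            l = floor
    return out, clamped


# ---------------------------------------------------------------------------
# vectorized python-facing wrappers

def force_length(l_ce, l_opt: float, w: float):
    """Active force-length multiplier (bell curve), vectorized."""
    x = np.abs((np.asarray(l_ce, dtype=float) - l_opt) / (l_opt * w))
    return np.exp(FL_LN * x ** 3)


def force_velocity(v, v_max_abs: float, K: float = FV_K, N: float = FV_N):
    """Force-velocity multiplier; v > 0 is lengthening."""
    v = np.asarray(v, dtype=float)
    s = np.clip(-v, 0.0, v_max_abs)
    conc = (v_max_abs - s) / (v_max_abs + K * s)
    ecc = N - (N - 1.0) * (v_max_abs + v) / (FV_ECC_SLOPE * K * v + v_max_abs)
    out = np.where(v <= 0.0, np.where(-v >= v_max_abs, 0.0, conc), ecc)
    return out if out.ndim else float(out)


def force_velocity_inverse(f, v_max_abs: float, K: float = FV_K, N: float = FV_N):
    """Velocity at which the force-velocity multiplier equals f (scalar)."""
    return _fv_inv(float(f), v_max_abs, K, N)


def parallel_force(l_ce, l_opt: float, w: float, F_max: float):
    """Parallel elastic force: engages only above the optimal length."""
    l_ce = np.asarray(l_ce, dtype=float)
    x = np.clip((l_ce - l_opt) / (l_opt * w), 0.0, None)
    out = F_max * x ** 2
    return out if out.ndim else float(out)


def tendon_force_scalar(lam: float, F_max: float, K_sh: float, lam_ref: float) -> float:
    return _fse(float(lam), F_max, K_sh, lam_ref)
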