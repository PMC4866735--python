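"""Muscle metabolic energetics (Umberger-style) and whole-body cost.

The per-muscle metabolic rate (W per kg of muscle) is the sum of four
terms: activation heat, maintenance heat, shortening/lengthening heat, and
the positive mechanical work rate of the contractile element,

    Edot = h_A + h_M + h_SL + w_CE.

Coefficients follow the widely used calibration in which the combined
activation+maintenance heat of a fully excited muscle is
128*FT + 25 W/kg (FT = fast-twitch fraction), split 40% activation
(length-independent) / 60% maintenance (scaled by the force-length factor
above optimal length). Shortening heat coefficients are
alpha_S(ST) = 100 / vtilde_max(ST) and alpha_S(FT) = 153 / vtilde_max(FT)
with vtilde_max(ST) = vtilde_max(FT)/2.5 (velocities in l_opt/s);
lengthening heat uses alpha_L = 4 * alpha_S(ST). Heats scale with the
excitation/activation factor A (A^0.6 for activation/maintenance, A^2 for
shortening, A for lengthening) and the aerobic factor S. Negative
contractile work is excluded (the work-rate term is floored at zero), so
every component is nonnegative.

All coefficients live in the UmbergerCoefficients table and can be
overridden per muscle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (GRAVITY, EnergeticsReport, GaitEvents, MTUParams,
                        MTUTrace, SubjectScalars)

__all__ = [
    "UmbergerCoefficients", "RHO_MUSCLE", "SIGMA_MUSCLE",
    "umberger_rate", "muscle_mass", "whole_body_cost", "phase_fractions",
    "positive_work_efficiency", "energetics_report",
]

RHO_MUSCLE = 1059.7  # kg/m^3, density of skeletal muscle
SIGMA_MUSCLE = 0.25e6  # Pa, specific tension of skeletal muscle


@dataclass(frozen=True)
class UmbergerCoefficients:
    """Named constants of the metabolic model (see module docstring)."""

    h_am_fast: float = 128.0  # W/kg per unit fast-twitch fraction
    h_am_base: float = 25.0  # W/kg
    act_share: float = 0.4  # activation share of h_AM
    alpha_slow_numerator: float = 100.0  # -> alpha_S(ST) = 100/vmax_ST
    alpha_fast_numerator: float = 153.0  # -> alpha_S(FT) = 153/vmax_FT
    slow_vmax_ratio: float = 2.5  # vmax_FT / vmax_ST
    lengthening_factor: float = 4.0  # alpha_L = factor * alpha_S(ST)
    aerobic_scale: float = 1.5  # S, walking value
    am_exponent: float = 0.6  # A^0.6 on activation/maintenance heat
    shortening_exponent: float = 2.0  # A^2 on shortening heat
    lengthening_exponent: float = 1.0  # A^1 on lengthening heat


DEFAULT_COEFFS = UmbergerCoefficients()


def _excitation_activation_factor(u, a):
    """Composite scaling factor A: u when u > a, else (u + a)/2."""
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    return np.where(u > a, u, 0.5 * (u + a))


def umberger_rate(u, a, l_ce, v_ce, F_ce, params: MTUParams,
                  coeffs: UmbergerCoefficients = DEFAULT_COEFFS,
                  ) -> dict[str, np.ndarray]:
    """Metabolic rate components (W/kg of muscle) at the given state(s).

    Parameters are broadcastable arrays: excitation u, activation a (both
    in [0, 1]), fascicle length l_ce (m), fascicle velocity v_ce (m/s,
    lengthening positive), and contractile force F_ce (N).

    Returns the four components 'h_A', 'h_M', 'h_SL', 'w_CE' plus 'total'.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if (np.any(~np.isfinite(u)) or np.any(~np.isfinite(a))
            or np.any((u < 0) | (u > 1)) or np.any((a < 0) | (a > 1))):
        raise ValueError("u and a must be finite and lie in [0, 1]")
    l_ce = np.asarray(l_ce, dtype=float)
    v_ce = np.asarray(v_ce, dtype=float)
    F_ce = np.asarray(F_ce, dtype=float)

    FT = params.FT
    A = _excitation_activation_factor(u, a)
    S = coeffs.aerobic_scale

    # force-length factor applied above optimal length
    from . import hill
    fl = hill.force_length(l_ce, params.l_opt, params.w)
    fl_factor = np.where(l_ce > params.l_opt, fl, 1.0)

    h_am = coeffs.h_am_fast * FT + coeffs.h_am_base
    A_am = A ** coeffs.am_exponent
    h_A = coeffs.act_share * h_am * A_am * S
    h_M = (1.0 - coeffs.act_share) * h_am * fl_factor * A_am * S

    vmax_ft = params.v_max  # l_opt/s
    vmax_st = vmax_ft / coeffs.slow_vmax_ratio
    alpha_st = coeffs.alpha_slow_numerator / vmax_st
    alpha_ft = coeffs.alpha_fast_numerator / vmax_ft
    alpha_len = coeffs.lengthening_factor * alpha_st

    v_norm = v_ce / params.l_opt  # l_opt/s, lengthening positive
    shortening = v_norm < 0
    h_sl_short = (alpha_st * (1.0 - FT) + alpha_ft * FT) * np.abs(v_norm) \
        * A ** coeffs.shortening_exponent
    h_sl_len = alpha_len * np.clip(v_norm, 0.0, None) \
        * A ** coeffs.lengthening_exponent
    h_SL = np.where(shortening, h_sl_short, h_sl_len) * fl_factor * S

    m_i = muscle_mass(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_CE = np.where(m_i > 0, np.clip(-F_ce * v_ce, 0.0, None) / max(m_i, 1e-300), 0.0)

    total = h_A + h_M + h_SL + w_CE
    return {"h_A": h_A, "h_M": h_M, "h_SL": h_SL, "w_CE": w_CE, "total": total}


def muscle_mass(params: MTUParams) -> float:
    """Muscle mass from strength and optimal length:
    M_i = rho * F_max * l_opt / sigma."""
    return RHO_MUSCLE * params.F_max * params.l_opt / SIGMA_MUSCLE


def whole_body_cost(muscle_energies: dict[str, float],
                    muscle_masses: dict[str, float],
                    scalars: SubjectScalars, T: float) -> tuple[float, float]:
    """Whole-body metabolic cost over a window T and the cost of transport.

    `muscle_energies` are J per window for ONE leg's muscles; bilateral
    symmetry doubles the muscle term. The remaining body mass is billed at
    the basal rate. MCOT = C_met / (M g v T), gross (basal included).
    """
    if T <= 0:
        raise ValueError("window T must be positive")
    m_mus = 2.0 * sum(muscle_masses.values())
    if m_mus >= scalars.body_mass:
        raise ValueError(f"muscle mass {m_mus:.1f} kg exceeds body mass")
    e_mus = 2.0 * sum(muscle_energies.values())
    c_met = e_mus + (scalars.body_mass - m_mus) * scalars.basal_rate * T
    distance = scalars.walking_speed * T
    mcot = c_met / (scalars.body_mass * GRAVITY * distance)
    return float(c_met), float(mcot)


def phase_fractions(time: np.ndarray, total_rate: np.ndarray,
                    events: GaitEvents) -> tuple[float, float, float]:
    """Fraction of muscle metabolic expenditure in the double-support,
    single-support, and swing phases of the cycle spanned by `time`.

    `total_rate` is the summed muscle metabolic power (any consistent
    units) on the uniform `time` grid covering one cycle [t0, t1).
    """
    time = np.asarray(time, dtype=float)
    total_rate = np.asarray(total_rate, dtype=float)
    dt = time[1] - time[0]
    t0 = float(time[0])
    t1 = float(time[-1] + dt)
    phases = events.phase_boundaries((t0, t1))
    total = float(np.sum(total_rate) * dt)
    if total <= 0:
        raise ValueError("total metabolic expenditure over the cycle is zero")

    def integrate(lo: float, hi: float) -> float:
        mask = (time >= lo) & (time < hi)
        return float(np.sum(total_rate[mask]) * dt)

    f_ds = (integrate(*phases["double_support_1"])
            + integrate(*phases["double_support_2"])) / total
    f_ss = integrate(*phases["single_support"]) / total
    f_sw = integrate(*phases["swing"]) / total
    return f_ds, f_ss, f_sw


def positive_work_efficiency(traces: dict[str, MTUTrace],
                             rate_totals: dict[str, np.ndarray],
                             params: dict[str, MTUParams]) -> float:
    """Efficiency of positive muscle work: total positive CE work divided
    by total muscle metabolic energy (muscle-only denominator, no basal).
    """
    num = 0.0
    den = 0.0
    for m, tr in traces.items():
        dt = tr.time[1] - tr.time[0]
        num += float(np.sum(np.clip(-tr.F_CE * tr.v_CE, 0.0, None)) * dt)
        den += muscle_mass(params[m]) * float(np.sum(rate_totals[m]) * dt)
    if den <= 0:
        raise ValueError("zero metabolic denominator")
    return num / den


def energetics_report(traces: dict[str, MTUTrace],
                      drives: dict[str, np.ndarray],
                      activations: dict[str, np.ndarray],
                      params: dict[str, MTUParams],
                      scalars: SubjectScalars,
                      events: GaitEvents | None = None,
                      coeffs: UmbergerCoefficients = DEFAULT_COEFFS,
                      ) -> EnergeticsReport:
    """Full energetic summary of a simulated gait cycle (one leg input,
    whole-body output under bilateral symmetry)."""
    masses = {m: muscle_mass(params[m]) for m in traces}
    energies: dict[str, float] = {}
    comp_means: dict[str, dict[str, float]] = {}
    rate_totals: dict[str, np.ndarray] = {}
    any_time = None
    for m, tr in traces.items():
        any_time = tr.time
        comps = umberger_rate(drives[m], activations[m], tr.l_CE, tr.v_CE,
                              tr.F_CE, params[m], coeffs)
        dt = tr.time[1] - tr.time[0]
        rate_totals[m] = comps["total"]
        energies[m] = masses[m] * float(np.sum(comps["total"]) * dt)
        comp_means[m] = {k: float(np.mean(v)) for k, v in comps.items()}
    T = any_time.size * float(any_time[1] - any_time[0])
    c_met, mcot = whole_body_cost(energies, masses, scalars, T)
    if events is not None:
        total_rate = sum(masses[m] * rate_totals[m] for m in traces)
        fractions = phase_fractions(any_time, total_rate, events)
    else:
        fractions = (float("nan"),) * 3
    eff = positive_work_efficiency(traces, rate_totals, params)
    return EnergeticsReport(
        muscle_mass=masses, muscle_energy=energies,
        rate_components=comp_means, C_met=c_met, mcot=mcot,
        phase_fractions=fractions, positive_work_efficiency=eff)
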