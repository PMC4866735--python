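"""Synthetic gait datasets with known ground truth.

This module stands in for a gait laboratory: it produces smooth periodic
joint kinematics, geometry-consistent muscle-tendon lengths and moment
arms, EMG generated from the jump-diffusion/exponential observation model
used by the drive estimator, and joint moments forward-simulated from a
known morphology vector. Because the generating morphology and drives are
recorded, every downstream stage (activation estimation, simulation,
identification, selection) can be scored against truth.

What is emulated: sagittal-plane walking at self-selected speed, one
average gait cycle of mechanics at 125 Hz plus several cycles of raw EMG
at 1000 Hz, heel-strike/toe-off events for both legs, and measurement
noise on the joint moments. What is not: marker trajectories, force-plate
raw signals, soft-tissue artifact, or out-of-sagittal-plane motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import emg as emg_mod
from . import energetics as en
from . import mtu as mtu_mod
from .datatypes import (Bounds, GaitDataset, GaitEvents, GroundTruth,
                        HFLParams, MorphologyVector, MTUParams,
                        SubjectScalars)
from .muscles import JOINT_WIRING, MUSCLES, MUSCLE_ORDER, muscles_for_joints

__all__ = [
    "KinematicsConfig", "default_scalars",
    "gen_kinematics_geometry", "gen_emg", "gen_drive_jump_diffusion",
    "gen_truth_params", "forward_generate", "make_subject",
    "drive_template", "gen_synthetic_front",
]


def default_scalars() -> SubjectScalars:
    """Study-typical subject: adult male walking at self-selected speed."""
    return SubjectScalars(body_mass=70.4, height=1.77, walking_speed=1.25,
                          basal_rate=1.5, gait_cycle_duration=1.1)


#: Joint angle Fourier templates: constant + [(harmonic k, amplitude rad,
#: phase as cycle fraction)], evaluated as c0 + sum A cos(2 pi k (phi - p)).
#: Hip flexes ~+0.45 rad around heel strike, extends past vertical
#: (negative) through late stance so the hip flexor ligament can engage;
#: knee shows the stance flexion wave and a large swing flexion peak; the
#: ankle dorsiflexes through mid-stance and plantarflexes at push-off.
ANGLE_TEMPLATES: dict[str, tuple[float, list[tuple[int, float, float]]]] = {
    "hip": (0.10, [(1, 0.35, 0.92), (2, 0.03, 0.35)]),
    "knee": (0.42, [(1, 0.33, 0.70), (2, 0.14, 0.36)]),
    "ankle": (-0.02, [(1, 0.11, 0.40), (2, 0.12, 0.33)]),
}

#: Drive bump templates per muscle: (center % GC, width, amplitude).
#: Timing follows the qualitative on/off pattern of walking (dorsiflexor
#: around heel strike and in swing, plantarflexors through mid-late
#: stance, knee extensors in early stance, hip flexors around toe-off,
#: hamstrings in terminal swing), without claiming subject-level fidelity.
DRIVE_TEMPLATES: dict[str, list[tuple[float, float, float]]] = {
    "TA": [(0.03, 0.14, 0.35), (0.80, 0.35, 0.30)],
    "SOL": [(0.28, 0.42, 0.55)],
    "GAS": [(0.50, 0.22, 0.60)],
    "VAS": [(0.04, 0.18, 0.45), (0.97, 0.10, 0.20)],
    "BFSH": [(0.90, 0.18, 0.25)],
    "RF": [(0.60, 0.18, 0.30), (0.08, 0.15, 0.15)],
    "HAM": [(0.97, 0.20, 0.45), (0.06, 0.18, 0.35)],
    "ILL": [(0.60, 0.22, 0.50)],
    "GMAX": [(0.06, 0.22, 0.40)],
    "GMED": [(0.25, 0.35, 0.35)],
    "ADDL": [(0.62, 0.25, 0.30)],
    "ADDM": [(0.05, 0.22, 0.30)],
}

DRIVE_BASELINE = 0.02


@dataclass(frozen=True)
class KinematicsConfig:
    """Grid rates, cycle structure, and randomization of the generator."""

    grid_rate: float = 125.0  # Hz, mechanics clock
    emg_rate: float = 1000.0  # Hz, EMG clock
    n_emg_cycles: int = 8  # cycles of raw EMG generated
    amplitude_jitter: float = 0.05  # relative seed-driven variation
    toe_off_fraction: float = 0.62  # ipsilateral toe-off, % GC
    contra_shift: float = 0.5  # contralateral half-cycle offset
    joints: tuple[str, ...] = ("ankle", "knee", "hip")
    moment_noise_rel: float = 0.02  # SD as fraction of per-joint range
    tendon_pretension_strain: float = 0.012  # mid-cycle tendon strain offset


def _fourier_angle(phi: np.ndarray, c0: float,
                   harmonics: list[tuple[int, float, float]],
                   amp_scale: float = 1.0) -> np.ndarray:
    out = np.full_like(phi, c0)
    for k, amp, phase in harmonics:
        out += amp_scale * amp * np.cos(2 * np.pi * k * (phi - phase))
    return out


def _excursion(theta: dict[str, np.ndarray], muscle: str) -> np.ndarray:
    """Path-independent MTU excursion integral sum_j int r_ij dtheta_j.

    With the linear moment-arm model r = r0 + r1*theta the integral is
    r0*theta + r1*theta^2/2, so l_MTC = L_ref - excursion is exactly
    consistent with ld_MTC = -sum_j r_ij(theta_j) thetad_j.
    """
    spec = MUSCLES[muscle]
    exc = np.zeros_like(next(iter(theta.values())))
    # joints absent from the reduced model are held at the reference angle
    # (zero excursion contribution)
    for j, (r0, r1) in spec.moment_arms.items():
        if j not in theta:
            continue
        th = theta[j]
        exc = exc + r0 * th + 0.5 * r1 * th ** 2
    return exc


def gen_kinematics_geometry(scalars: SubjectScalars | None = None,
                            seed: int = 0,
                            config: KinematicsConfig = KinematicsConfig(),
                            muscles: tuple[str, ...] | None = None,
                            ) -> GaitDataset:
    """Generate the kinematic/geometric half of a dataset.

    Joint angles are truncated Fourier series; moment arms are linear in
    joint angle with anatomical signs; MTU lengths follow from the
    excursion integral so geometry is self-consistent. Joint moments and
    EMG are left zero (filled by forward_generate).
    """
    scalars = scalars or default_scalars()
    if config.grid_rate <= 0 or config.emg_rate <= 0:
        raise ValueError("grid rates must be positive")
    if scalars.gait_cycle_duration <= 0:
        raise ValueError("cycle duration must be positive")
    rng = np.random.default_rng(seed)
    T = scalars.gait_cycle_duration
    n = int(round(config.grid_rate * T))
    time = np.arange(n) / config.grid_rate
    phi = time / T

    theta: dict[str, np.ndarray] = {}
    for j in config.joints:
        c0, harm = ANGLE_TEMPLATES[j]
        scale = 1.0 + config.amplitude_jitter * rng.uniform(-1, 1)
        theta[j] = _fourier_angle(phi, c0, harm, scale)

    muscles = muscles or muscles_for_joints(config.joints)
    mtu_lengths: dict[str, np.ndarray] = {}
    moment_arms: dict[str, dict[str, np.ndarray]] = {}
    for m in muscles:
        spec = MUSCLES[m]
        exc = _excursion(theta, m)
        # anchor: mid-excursion state has the fascicle at optimal length and
        # the tendon lightly pretensioned
        l_ref = (spec.l_sl_ref * (1.0 + config.tendon_pretension_strain)
                 + spec.l_opt_ref * math.cos(spec.theta0)
                 + float(np.mean(exc)))
        mtu_lengths[m] = l_ref - exc
        moment_arms[m] = {j: spec.moment_arms[j][0] + spec.moment_arms[j][1] * theta[j]
                          for j in spec.moment_arms if j in config.joints}

    n_cyc = config.n_emg_cycles
    emg_time = np.arange(int(round(n_cyc * T * config.emg_rate))) / config.emg_rate
    k = np.arange(n_cyc + 1)
    events = GaitEvents(
        heel_strikes=k * T,
        toe_offs=(k[:-1] + config.toe_off_fraction) * T,
        contra_heel_strikes=(k[:-1] + config.contra_shift) * T,
        # contralateral toe-off precedes ipsilateral single support:
        # at (shift + toe_off_fraction - 1) into each cycle (12% GC default)
        contra_toe_offs=(k[:-1] + config.contra_shift
                         + config.toe_off_fraction - 1.0) * T,
    )
    return GaitDataset(
        time=time, joint_angles=theta, mtu_lengths=mtu_lengths,
        moment_arms=moment_arms,
        joint_moments={j: np.zeros(n) for j in config.joints},
        emg_time=emg_time, emg={}, events=events, scalars=scalars)


def drive_template(muscle: str, phi: np.ndarray,
                   baseline: float = DRIVE_BASELINE) -> np.ndarray:
    """Evaluate a muscle's periodic drive template at cycle fractions phi."""
    x = np.full_like(np.asarray(phi, dtype=float), baseline)
    for center, width, amp in DRIVE_TEMPLATES[muscle]:
        d = (np.asarray(phi) - center + 0.5) % 1.0 - 0.5
        mask = np.abs(d) < width / 2
        x = x + np.where(mask, amp * 0.5 * (1 + np.cos(2 * np.pi * d / width)), 0.0)
    return np.clip(x, 0.0, 1.0)


def gen_emg(drive: np.ndarray, fs: float = 1000.0, seed: int = 0,
            signed: bool = False) -> np.ndarray:
    """Draw raw EMG from the exponential observation law with mean x(t).

    Each sample is exponentially distributed with scale equal to the
    instantaneous drive (zero drive yields zero signal); `signed` flips a
    random +-1 to emulate an unrectified recording.
    """
    x = np.asarray(drive, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("drive must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.where(x > 0, rng.exponential(size=x.shape) * x, 0.0)
    if signed:
        out = out * rng.choice([-1.0, 1.0], size=x.shape)
    return out


def gen_drive_jump_diffusion(n: int, dt: float, alpha: float = 0.5,
                             beta: float = 1.0, seed: int = 0,
                             x0: float = 0.5) -> np.ndarray:
    """Simulate the latent jump-diffusion drive model.

    dx = alpha dW + (U - x) dN_beta: Brownian motion of rate alpha with
    Poisson (rate beta per unit time) jumps to a uniform level, clipped
    to [0, 1].
    """
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = x0
    noise = rng.normal(0.0, alpha * math.sqrt(dt), size=n)
    jumps = rng.random(n) < beta * dt
    targets = rng.random(n)
    for i in range(1, n):
        v = targets[i] if jumps[i] else x[i - 1] + noise[i]
        x[i] = min(1.0, max(0.0, v))
    return x


def gen_truth_params(bounds: Bounds, seed: int = 0,
                     margin: float = 0.15,
                     max_rejections: int = 10_000) -> MorphologyVector:
    """Draw a ground-truth morphology uniformly strictly inside bounds.

    `margin` shrinks the box toward its center (a truth at 15% inset keeps
    recovery tests meaningful without hugging a bound). Fascicle-range
    feasibility is inherited from the bounds construction, which restricts
    the length-scale interval per muscle; draws additionally rejected if
    any degenerate parameter combination yields a non-finite vector.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    span = hi - lo
    lo_in = lo + margin * span
    hi_in = hi - margin * span
    for _ in range(max_rejections):
        v = rng.uniform(lo_in, hi_in)
        if np.all(np.isfinite(v)):
            return MorphologyVector(muscles=bounds.muscles, values=v,
                                    has_ligament=bounds.has_ligament)
    raise RuntimeError("could not draw feasible truth parameters")


def params_from_vector(vec: MorphologyVector) -> tuple[dict[str, MTUParams],
                                                       HFLParams | None]:
    """Expand a morphology vector into per-muscle MTUParams (registry
    reference lengths scaled by the vector's length_scale)."""
    params: dict[str, MTUParams] = {}
    for m in vec.muscles:
        block = vec.muscle_block(m)
        spec = MUSCLES[m]
        params[m] = MTUParams(
            name=m, F_max=block["F_max"],
            l_opt=spec.l_opt_ref * block["length_scale"],
            l_sl=spec.l_sl_ref * block["length_scale"],
            K_sh=block["K_sh"], lambda_ref=block["lambda_ref"],
            theta0=spec.theta0, w=spec.w, v_max=spec.v_max, FT=spec.FT,
            tau_act=spec.tau_act, tau_deact=spec.tau_deact)
    hfl = vec.hfl if vec.has_ligament else None
    return params, hfl


def forward_generate(truth: MorphologyVector, partial: GaitDataset,
                     seed: int = 0,
                     moment_noise_rel: float = 0.02,
                     act_cfgs: dict[str, emg_mod.ActivationConfig] | None = None,
                     ) -> tuple[GaitDataset, GroundTruth]:
    """Close the loop: simulate the truth morphology on the partial dataset
    and emit a complete noisy dataset plus its ground truth.

    Joint moments are the modeled moments plus Gaussian noise with SD
    equal to `moment_noise_rel` times the per-joint range; raw EMG is
    drawn from the exponential observation law around each muscle's drive
    template; activations are the drive passed through the activation
    dynamics.
    """
    rng = np.random.default_rng(seed)
    T = partial.scalars.gait_cycle_duration
    phi = partial.time / T
    params, hfl = params_from_vector(truth)

    drives: dict[str, np.ndarray] = {}
    activations: dict[str, np.ndarray] = {}
    for m in truth.muscles:
        x = drive_template(m, phi)
        cfg = (act_cfgs or {}).get(m) or emg_mod.ActivationConfig(
            tau_act=params[m].tau_act, tau_deact=params[m].tau_deact,
            threshold=0.0)
        drives[m] = x
        activations[m] = emg_mod.activation_dynamics(partial.time, x, cfg)

    traces, tau = mtu_mod.simulate_leg(partial, activations, params, hfl=hfl)
    moments: dict[str, np.ndarray] = {}
    for j, series in tau.items():
        rng_span = float(np.ptp(series))
        sd = moment_noise_rel * rng_span
        moments[j] = series + (rng.normal(0.0, sd, size=series.shape)
                               if sd > 0 else 0.0)

    emg_phi = (partial.emg_time % T) / T
    emg_channels = {m: gen_emg(drive_template(m, emg_phi), seed=int(rng.integers(2 ** 31)))
                    for m in truth.muscles}

    report = en.energetics_report(traces, drives, activations, params,
                                  partial.scalars, events=partial.events)
    dataset = GaitDataset(
        time=partial.time.copy(), joint_angles=dict(partial.joint_angles),
        mtu_lengths=dict(partial.mtu_lengths),
        moment_arms=dict(partial.moment_arms), joint_moments=moments,
        emg_time=partial.emg_time.copy(), emg=emg_channels,
        events=partial.events, scalars=partial.scalars)
    gt = GroundTruth(morphology=truth, drive_signals=drives,
                     activations=activations, metabolic_cost=report.C_met,
                     mcot=report.mcot)
    return dataset, gt


def make_subject(seed: int = 0, joints: tuple[str, ...] = ("ankle", "knee", "hip"),
                 moment_noise_rel: float = 0.02,
                 config: KinematicsConfig | None = None,
                 ) -> tuple[GaitDataset, GroundTruth, Bounds]:
    """One-call synthetic subject: geometry, bounds, truth, forward data.

    Restricting `joints` yields the reduced problems used for scaled-down
    recovery studies (e.g. ("ankle",) gives the 3-muscle single-joint
    problem with no hip ligament).
    """
    from .identify import build_bounds  # local import to avoid a cycle

    config = config or KinematicsConfig(joints=tuple(joints),
                                        moment_noise_rel=moment_noise_rel)
    partial = gen_kinematics_geometry(seed=seed, config=config)
    reference_F = {m: MUSCLES[m].F_max_ref for m in partial.muscles}
    include_lig = "hip" in joints
    bounds = build_bounds(partial, reference_F, include_ligament=include_lig)
    truth = gen_truth_params(bounds, seed=seed + 1)
    dataset, gt = forward_generate(truth, partial, seed=seed + 2,
                                   moment_noise_rel=moment_noise_rel)
    return dataset, gt, bounds


# ---------------------------------------------------------------------------
# synthetic Pareto fronts (selection-stage test material)

def gen_synthetic_front(seed: int = 0, n: int = 40,
                        r2_range: tuple[float, float] = (0.55, 0.97),
                        tail_start: float = 0.9, base_vas: float = 0.20,
                        tail_vas: float = 0.45, c_truth: float = 300.0,
                        noise: float = 0.004) -> tuple[list, float]:
    """A synthetic identification front with a planted overfit tail.

    Fractional vastus cost is flat at `base_vas` for most of the front and
    ramps to `tail_vas` in the top (1 - tail_start) share of the R^2 span,
    mimicking the non-physical regime where the optimizer sinks energy into
    one muscle for marginal kinetic gains. The vastus share responds
    promptly at the tail's onset (concave rise) while the whole-body
    metabolic cost blows up only deep in the tail (quartic rise) - the
    L-shaped front geometry the budget cutoff is designed for. Ground
    truth sits at the base of the ramp. Returns (solutions, truth C_met).
    """
    from .datatypes import ParetoSolution

    rng = np.random.default_rng(seed)
    r_lo, r_hi = r2_range
    r2 = np.sort(rng.uniform(r_lo, r_hi, size=n))
    ramp = np.clip((r2 - (r_lo + tail_start * (r_hi - r_lo)))
                   / ((1 - tail_start) * (r_hi - r_lo)), 0.0, 1.0)
    f_vas = base_vas + (tail_vas - base_vas) * np.sqrt(ramp) \
        + rng.normal(0, noise, size=n)
    c_met = c_truth * (1.0 + 0.06 * (r2 - r_lo) / (r_hi - r_lo)
                       + 0.8 * ramp ** 4) + rng.normal(0, 2.0, size=n)

    sols = []
    other = [m for m in MUSCLE_ORDER if m != "VAS"]
    dummy = MorphologyVector(
        muscles=MUSCLE_ORDER,
        values=np.concatenate([np.tile([1000.0, 1.0, 3.0, 0.05],
                                       len(MUSCLE_ORDER)), [200.0, 0.0]]))
    for i in range(n):
        fv = float(np.clip(f_vas[i], 0.0, 0.9))
        rest = (0.75 - fv) / len(other)  # remainder split evenly; 0.25 basal
        fractions = {m: rest for m in other}
        fractions["VAS"] = fv
        sols.append(ParetoSolution(
            vector=dummy, C_met=float(c_met[i]), mcot=float(c_met[i] / 900.0),
            C_kin=float(1.0 - r2[i]), mean_R2=float(r2[i]),
            per_joint_R2={"ankle": float(r2[i])}, muscle_fractions=fractions))
    # truth = metabolic cost at the base of the overfit ramp
    return sols, float(c_truth * (1.0 + 0.06 * tail_start))
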