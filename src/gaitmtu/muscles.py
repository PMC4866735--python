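"""Registry of the twelve lumped sagittal-plane leg actuators.

The model covers the muscles that contribute significant sagittal torque at
the ankle, knee, and hip during walking, with anatomically grouped actuators
(GAS = medial+lateral gastrocnemius, VAS = the three vasti, HAM = the three
long hamstrings, ILL = iliacus+psoas), plus a passive hip flexor ligament.

Sign conventions (documented here because they are not universal):
  * hip flexion positive, knee flexion positive, ankle dorsiflexion positive;
  * a muscle's moment arm r_ij carries the sign of the torque it produces
    about joint j (tau = F * r), so flexors/dorsiflexors have r > 0;
  * MTU length shortens when a joint moves in the muscle's pull direction:
    d l_MTC / dt = - sum_j r_ij(theta_j) * dtheta_j/dt.

Moment arms are modeled as linear functions of the joint angle,
r(theta) = r0 + r1 * theta, which keeps the geometry integrable in closed
form while capturing first-order angle dependence.

Reference morphology (l_opt, l_sl, pennation, fiber composition, F_max) is
literature-typical adult male anatomy; the identification stage rescales
F_max and the (l_sl, l_opt) pair per subject, so these serve as anchors,
not as claims about any individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MTUParams

__all__ = [
    "MUSCLES",
    "MUSCLE_ORDER",
    "JOINTS",
    "MuscleSpec",
    "reference_params",
    "muscles_for_joints",
]

JOINTS = ("ankle", "knee", "hip")


@dataclass(frozen=True)
class MuscleSpec:
    """Static description of one lumped actuator."""

    name: str
    #: joint -> (r0, r1) of the linear moment-arm model r = r0 + r1*theta  [m, m/rad]
    moment_arms: dict[str, tuple[float, float]]
    F_max_ref: float  # N
    l_opt_ref: float  # m
    l_sl_ref: float  # m
    theta0: float  # rad, pennation at optimal length
    w: float  # force-length width
    FT: float  # fast-twitch fraction
    tau_act: float  # s

    @property
    def tau_deact(self) -> float:
        # deactivation is slower than activation; factor 4 is the package
        # default (configurable per muscle via MTUParams)
        return 4.0 * self.tau_act

    @property
    def v_max(self) -> float:
        """Maximal shortening velocity in l_opt/s, from fiber composition."""
        return 6.0 + 6.0 * self.FT

    @property
    def joints(self) -> tuple[str, ...]:
        return tuple(self.moment_arms)


def _deg(x: float) -> float:
    return float(np.deg2rad(x))


# The registry. Moment-arm magnitudes are centimeter-scale values typical of
# adult anatomy; signs follow the conventions in the module docstring.
MUSCLES: dict[str, MuscleSpec] = {
    "TA": MuscleSpec(  # tibialis anterior: ankle dorsiflexor
        "TA", {"ankle": (0.040, -0.006)},
        F_max_ref=600.0, l_opt_ref=0.098, l_sl_ref=0.223,
        theta0=_deg(5.0), w=0.50, FT=0.27, tau_act=0.012),
    "SOL": MuscleSpec(  # soleus: ankle plantarflexor, slow-dominant
        "SOL", {"ankle": (-0.050, 0.008)},
        F_max_ref=3500.0, l_opt_ref=0.050, l_sl_ref=0.250,
        theta0=_deg(25.0), w=0.56, FT=0.19, tau_act=0.018),
    "GAS": MuscleSpec(  # gastrocnemius group: plantarflexor + knee flexor
        "GAS", {"ankle": (-0.042, 0.005), "knee": (0.018, -0.004)},
        F_max_ref=1900.0, l_opt_ref=0.060, l_sl_ref=0.390,
        theta0=_deg(17.0), w=0.56, FT=0.45, tau_act=0.012),
    "VAS": MuscleSpec(  # vastus group: knee extensor
        "VAS", {"knee": (-0.042, 0.006)},
        F_max_ref=4500.0, l_opt_ref=0.087, l_sl_ref=0.130,
        theta0=_deg(4.0), w=0.50, FT=0.50, tau_act=0.012),
    "BFSH": MuscleSpec(  # biceps femoris short head: knee flexor
        "BFSH", {"knee": (0.025, -0.004)},
        F_max_ref=350.0, l_opt_ref=0.173, l_sl_ref=0.100,
        theta0=_deg(23.0), w=0.50, FT=0.35, tau_act=0.012),
    "RF": MuscleSpec(  # rectus femoris: hip flexor + knee extensor
        "RF", {"knee": (-0.038, 0.005), "hip": (0.034, -0.004)},
        F_max_ref=750.0, l_opt_ref=0.084, l_sl_ref=0.346,
        theta0=_deg(5.0), w=0.50, FT=0.55, tau_act=0.012),
    "HAM": MuscleSpec(  # long hamstrings: hip extensor + knee flexor
        "HAM", {"knee": (0.030, -0.005), "hip": (-0.060, 0.006)},
        F_max_ref=1400.0, l_opt_ref=0.080, l_sl_ref=0.359,
        theta0=_deg(15.0), w=0.50, FT=0.40, tau_act=0.012),
    "ILL": MuscleSpec(  # iliacus + psoas: hip flexor
        "ILL", {"hip": (0.035, -0.005)},
        F_max_ref=800.0, l_opt_ref=0.100, l_sl_ref=0.090,
        theta0=_deg(7.0), w=0.50, FT=0.50, tau_act=0.012),
    "GMAX": MuscleSpec(  # gluteus maximus (GLU): hip extensor
        "GMAX", {"hip": (-0.055, 0.007)},
        F_max_ref=1200.0, l_opt_ref=0.142, l_sl_ref=0.125,
        theta0=_deg(5.0), w=0.55, FT=0.45, tau_act=0.012),
    "GMED": MuscleSpec(  # gluteus medius (HAB): small sagittal extensor arm
        "GMED", {"hip": (-0.012, 0.002)},
        F_max_ref=1300.0, l_opt_ref=0.054, l_sl_ref=0.078,
        theta0=_deg(8.0), w=0.50, FT=0.45, tau_act=0.012),
    "ADDL": MuscleSpec(  # adductor longus: weak hip flexor in the sagittal plane
        "ADDL", {"hip": (0.016, -0.003)},
        F_max_ref=430.0, l_opt_ref=0.138, l_sl_ref=0.110,
        theta0=_deg(6.0), w=0.50, FT=0.55, tau_act=0.012),
    "ADDM": MuscleSpec(  # adductor magnus: weak hip extensor in the sagittal plane
        "ADDM", {"hip": (-0.020, 0.003)},
        F_max_ref=870.0, l_opt_ref=0.087, l_sl_ref=0.060,
        theta0=_deg(5.0), w=0.50, FT=0.45, tau_act=0.012),
}

#: Canonical ordering, used for the 50-element morphology vector.
MUSCLE_ORDER = ("TA", "SOL", "GAS", "VAS", "BFSH", "RF",
                "HAM", "ILL", "GMAX", "GMED", "ADDL", "ADDM")

#: joint -> muscles that span it (moment wiring of the leg model)
JOINT_WIRING = {
    "ankle": ("TA", "SOL", "GAS"),
    "knee": ("GAS", "VAS", "BFSH", "RF", "HAM"),
    "hip": ("RF", "HAM", "ILL", "GMAX", "GMED", "ADDL", "ADDM"),
}


def muscles_for_joints(joints: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Muscles spanning any of the given joints, in canonical order."""
    keep = set()
    for j in joints:
        keep.update(JOINT_WIRING[j])
    return tuple(m for m in MUSCLE_ORDER if m in keep)


def reference_params(name: str, F_max: float | None = None,
                     length_scale: float = 1.0,
                     K_sh: float = 3.0, lambda_ref: float = 0.05) -> MTUParams:
    """Build MTUParams for a muscle from its registry reference morphology.

    F_max defaults to the registry reference; length_scale jointly rescales
    (l_opt, l_sl); the tendon material parameters default to mid-range.
    """
    spec = MUSCLES[name]
    return MTUParams(
        name=name,
        F_max=spec.F_max_ref if F_max is None else F_max,
        l_opt=spec.l_opt_ref * length_scale,
        l_sl=spec.l_sl_ref * length_scale,
        K_sh=K_sh,
        lambda_ref=lambda_ref,
        theta0=spec.theta0,
        w=spec.w,
        v_max=spec.v_max,
        FT=spec.FT,
        tau_act=spec.tau_act,
        tau_deact=spec.tau_deact,
    )
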