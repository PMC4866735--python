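"""Core data containers for the muscle-tendon identification pipeline.

All quantities are SI unless noted: lengths in m, forces in N, torques in
N*m, angles in rad (hip flexion positive, knee flexion positive, ankle
dorsiflexion positive), times in s, metabolic rates in W/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

__all__ = [
    "SubjectScalars",
    "GaitEvents",
    "GaitDataset",
    "GroundTruth",
    "MTUParams",
    "HFLParams",
    "MTUTrace",
    "MorphologyVector",
    "Bounds",
    "ParetoSolution",
    "EnergeticsReport",
    "BudgetCurve",
]

GRAVITY = 9.81  # m/s^2, used in the cost-of-transport denominator


@dataclass
class SubjectScalars:
    """Per-subject scalar quantities.

    basal_rate is the standing metabolic rate per unit body mass (W/kg);
    measured values for healthy adults cluster in the 1.3-1.7 W/kg band.
    """

    body_mass: float  # kg
    height: float  # m
    walking_speed: float  # m/s
    basal_rate: float  # W/kg
    gait_cycle_duration: float  # s

    def __post_init__(self) -> None:
        for name in ("body_mass", "height", "walking_speed", "basal_rate",
                     "gait_cycle_duration"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SubjectScalars.{name} must be strictly positive, got {v}")


@dataclass
class GaitEvents:
    """Gait events for both legs on the dataset clock.

    Heel strikes of the ipsilateral (recorded) leg anchor the gait cycle;
    the contralateral events partition each cycle into first double support,
    single support, second double support, and swing.
    """

    heel_strikes: np.ndarray  # ipsilateral, s
    toe_offs: np.ndarray  # ipsilateral, s
    contra_heel_strikes: np.ndarray  # contralateral, s
    contra_toe_offs: np.ndarray  # contralateral, s

    def __post_init__(self) -> None:
        for name in ("heel_strikes", "toe_offs", "contra_heel_strikes",
                     "contra_toe_offs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 1 or (arr.size > 1 and np.any(np.diff(arr) <= 0)):
                raise ValueError(f"GaitEvents.{name} must be strictly increasing 1-D")

    def cycles(self) -> list[tuple[float, float]]:
        """Complete (heel strike, next heel strike) intervals."""
        hs = self.heel_strikes
        return [(hs[i], hs[i + 1]) for i in range(len(hs) - 1)]

    def phase_boundaries(self, cycle: tuple[float, float]) -> dict[str, tuple[float, float]]:
        """Partition one cycle into the four classic phases (ipsilateral view).

        Double support is reported as the union of the two double-support
        intervals; the returned dict tiles [t0, t1].
        """
        t0, t1 = cycle
        cto = self.contra_toe_offs[(self.contra_toe_offs > t0) & (self.contra_toe_offs < t1)]
        chs = self.contra_heel_strikes[(self.contra_heel_strikes > t0) & (self.contra_heel_strikes < t1)]
        to = self.toe_offs[(self.toe_offs > t0) & (self.toe_offs < t1)]
        if len(cto) != 1 or len(chs) != 1 or len(to) != 1:
            raise ValueError("events do not tile the cycle: need one contralateral "
                             "toe-off, one contralateral heel strike and one "
                             "ipsilateral toe-off inside each cycle")
        if not (t0 < cto[0] < chs[0] < to[0] < t1):
            raise ValueError("event ordering within cycle is not DS1, SS, DS2, swing")
        return {
            "double_support_1": (t0, float(cto[0])),
            "single_support": (float(cto[0]), float(chs[0])),
            "double_support_2": (float(chs[0]), float(to[0])),
            "swing": (float(to[0]), t1),
        }


@dataclass
class GaitDataset:
    """One subject's processed gait data: the pipeline's universal input.

    Mechanics channels (angles, MTU lengths, moment arms, joint moments)
    share the `time` clock; EMG lives on its own, faster `emg_time` clock.
    """

    time: np.ndarray  # s, uniform grid (mechanics clock)
    joint_angles: dict[str, np.ndarray]  # rad, per joint
    mtu_lengths: dict[str, np.ndarray]  # m, per muscle
    moment_arms: dict[str, dict[str, np.ndarray]]  # m, [muscle][joint]
    joint_moments: dict[str, np.ndarray]  # N*m, per joint (tau_exp)
    emg_time: np.ndarray  # s
    emg: dict[str, np.ndarray]  # normalized a.u., per muscle
    events: GaitEvents
    scalars: SubjectScalars

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing 1-D")
        self.time = t
        n = t.size
        for name, group in (("joint_angles", self.joint_angles),
                            ("mtu_lengths", self.mtu_lengths),
                            ("joint_moments", self.joint_moments)):
            for k, v in group.items():
                v = np.asarray(v, dtype=float)
                group[k] = v
                if v.shape != (n,):
                    raise ValueError(f"{name}[{k}] length {v.shape} != time grid {n}")
        for m, v in self.mtu_lengths.items():
            if np.any(v <= 0):
                raise ValueError(f"mtu_lengths[{m}] must be strictly positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def joints(self) -> list[str]:
        return list(self.joint_angles)

    @property
    def muscles(self) -> list[str]:
        return list(self.mtu_lengths)


@dataclass
class GroundTruth:
    """What the synthetic generator knows and the pipeline must recover."""

    morphology: "MorphologyVector"
    drive_signals: dict[str, np.ndarray]  # true x(t), mechanics grid, [0,1]
    activations: dict[str, np.ndarray]  # true a(t), mechanics grid, [0,1]
    metabolic_cost: float  # J per cycle (C_met)
    mcot: float


@dataclass
class MTUParams:
    """Morphology of one lumped muscle-tendon actuator.

    v_max is expressed in optimal lengths per second (converted to m/s
    internally); FT is the fast-twitch fiber fraction in [0, 1]; w is the
    half-width of the active force-length bell in units of l_opt.
    """

    name: str
    F_max: float  # N
    l_opt: float  # m
    l_sl: float  # m
    K_sh: float  # tendon shape factor, dimensionless
    lambda_ref: float  # tendon reference strain, dimensionless
    theta0: float = 0.0  # rad, pennation at l_CE = l_opt
    w: float = 0.56  # force-length width
    v_max: float = 10.0  # l_opt / s
    FT: float = 0.5  # fast-twitch fraction
    tau_act: float = 0.012  # s
    tau_deact: float = 0.048  # s

    def __post_init__(self) -> None:
        if self.F_max < 0:
            raise ValueError(f"{self.name}: F_max must be >= 0")
        if self.l_opt <= 0 or self.l_sl <= 0:
            raise ValueError(f"{self.name}: l_opt and l_sl must be positive")
        if not (0 < self.w < 1):
            raise ValueError(f"{self.name}: w must be in (0, 1)")
        if self.v_max <= 0:
            raise ValueError(f"{self.name}: v_max must be positive")
        if not (0 <= self.FT <= 1):
            raise ValueError(f"{self.name}: FT must be in [0, 1]")

    @property
    def v_max_abs(self) -> float:
        """Maximal shortening speed in m/s."""
        return self.v_max * self.l_opt

    def scaled(self, length_scale: float) -> "MTUParams":
        """Return a copy with (l_opt, l_sl) jointly multiplied by length_scale."""
        d = asdict(self)
        d["l_opt"] = self.l_opt * length_scale
        d["l_sl"] = self.l_sl * length_scale
        return MTUParams(**d)


@dataclass
class HFLParams:
    """Lumped hip flexor ligament: linear rotary spring engaging in extension."""

    K_HFL: float  # N*m/rad
    theta0_HFL: float  # rad, engagement angle (flexion positive)

    def __post_init__(self) -> None:
        if self.K_HFL < 0:
            raise ValueError("K_HFL must be >= 0")


@dataclass
class MTUTrace:
    """Simulated state and force trajectories for one muscle over one cycle.

    Sign convention: v_CE > 0 is lengthening (eccentric motion).
    """

    name: str
    time: np.ndarray  # s
    l_CE: np.ndarray  # m
    v_CE: np.ndarray  # m/s
    theta: np.ndarray  # rad, pennation
    F_CE: np.ndarray  # N
    F_PE: np.ndarray  # N
    F_SE: np.ndarray  # N
    lam: np.ndarray  # tendon strain
    clamped: int = 0  # velocity-clamp count during integration (diagnostic)

    @property
    def F_MTC(self) -> np.ndarray:
        return self.F_SE


# ---------------------------------------------------------------------------
# Identification containers

#: Free parameters per muscle, in vector order.
PER_MUSCLE_PARAMS = ("F_max", "length_scale", "K_sh", "lambda_ref")


@dataclass
class MorphologyVector:
    """The flat optimization vector: 4 parameters per muscle (+ 2 ligament).

    Ordering is muscle-major in the order of `muscles`, each contributing
    (F_max, length_scale, K_sh, lambda_ref), followed by (K_HFL, theta0_HFL)
    when the ligament is included. For the full 12-muscle leg model this is
    the 50-element vector.
    """

    muscles: tuple[str, ...]
    values: np.ndarray
    has_ligament: bool = True

    def __post_init__(self) -> None:
        self.muscles = tuple(self.muscles)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.size,):
            raise ValueError(
                f"MorphologyVector needs {self.size} values for "
                f"{len(self.muscles)} muscles (got {self.values.shape})")

    @property
    def size(self) -> int:
        return 4 * len(self.muscles) + (2 if self.has_ligament else 0)

    def muscle_block(self, name: str) -> dict[str, float]:
        i = self.muscles.index(name)
        block = self.values[4 * i:4 * i + 4]
        return dict(zip(PER_MUSCLE_PARAMS, block.tolist()))

    @property
    def hfl(self) -> HFLParams:
        if not self.has_ligament:
            raise ValueError("vector has no ligament block")
        return HFLParams(K_HFL=float(self.values[-2]), theta0_HFL=float(self.values[-1]))

    def to_dict(self) -> dict:
        d = {m: self.muscle_block(m) for m in self.muscles}
        if self.has_ligament:
            d["HFL"] = {"K_HFL": float(self.values[-2]),
                        "theta0_HFL": float(self.values[-1])}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyVector":
        muscles = tuple(k for k in d if k != "HFL")
        vals: list[float] = []
        for m in muscles:
            vals.extend(float(d[m][p]) for p in PER_MUSCLE_PARAMS)
        has_lig = "HFL" in d
        if has_lig:
            vals.extend([float(d["HFL"]["K_HFL"]), float(d["HFL"]["theta0_HFL"])])
        return cls(muscles=muscles, values=np.array(vals), has_ligament=has_lig)


@dataclass
class Bounds:
    """Elementwise box bounds for a MorphologyVector."""

    muscles: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    has_ligament: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        # equality is allowed: a degenerate interval pins that parameter
        if np.any(self.lower > self.upper):
            bad = np.nonzero(self.lower > self.upper)[0]
            raise ValueError(f"lower > upper at indices {bad.tolist()}")

    @property
    def size(self) -> int:
        return self.lower.size

    def contains(self, vec: MorphologyVector | np.ndarray, atol: float = 1e-12) -> bool:
        v = vec.values if isinstance(vec, MorphologyVector) else np.asarray(vec)
        return bool(np.all(v >= self.lower - atol) and np.all(v <= self.upper + atol))


@dataclass
class ParetoSolution:
    """One candidate on the identification Pareto front."""

    vector: MorphologyVector
    C_met: float  # J per evaluation window
    mcot: float
    C_kin: float  # 1 - mean R^2
    mean_R2: float
    per_joint_R2: dict[str, float]
    muscle_fractions: dict[str, float]  # share of C_met, both legs, basal included
    diagnostics: dict = field(default_factory=dict)


@dataclass
class EnergeticsReport:
    """Whole-body energetic summary for one evaluation window."""

    muscle_mass: dict[str, float]  # kg, one leg
    muscle_energy: dict[str, float]  # J per window, one leg
    rate_components: dict[str, dict[str, float]]  # mean W/kg per component
    C_met: float  # J, both legs + basal
    mcot: float
    phase_fractions: tuple[float, float, float]  # (double, single, swing)
    positive_work_efficiency: float


@dataclass
class BudgetCurve:
    """Quintic fit of one muscle's fractional metabolic cost vs mean R^2."""

    muscle: str
    coeffs: np.ndarray  # np.polynomial convention, low order first
    r2_min: float
    r2_max: float

    def __call__(self, r2: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(r2, self.coeffs)
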