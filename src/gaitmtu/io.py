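"""Readers and writers for dataset directories, parameter files, and
pipeline configuration.

A dataset directory holds plain-text files only:

    timeseries.csv   mechanics clock: time, angle_<joint>, moment_<joint>,
                     mtu_length_<muscle>, moment_arm_<muscle>_<joint>
    emg.csv          EMG clock: time + one column per muscle
    events.json      heel strikes / toe-offs for both legs (s)
    subject.json     body mass, height, walking speed, basal rate, cycle T
    truth_params.json  (optional) generating morphology, for synthetic data

All units are SI; numeric round-trips are lossless to float precision
(full repr written).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (GaitDataset, GaitEvents, MorphologyVector,
                        SubjectScalars)

__all__ = [
    "write_dataset", "read_dataset", "write_params", "read_params",
    "load_participant", "PipelineConfig",
]

_PARAM_RANGES = {"K_sh": (2.0, 5.0), "lambda_ref": (0.02, 0.09),
                 "F_max": (0.0, np.inf), "length_scale": (0.0, np.inf)}


def write_dataset(dataset: GaitDataset, path: str | Path) -> Path:
    """Write a dataset directory (see module docstring for layout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols: dict[str, np.ndarray] = {"time": dataset.time}
    for j, v in dataset.joint_angles.items():
        cols[f"angle_{j}"] = v
    for j, v in dataset.joint_moments.items():
        cols[f"moment_{j}"] = v
    for m, v in dataset.mtu_lengths.items():
        cols[f"mtu_length_{m}"] = v
    for m, per_joint in dataset.moment_arms.items():
        for j, v in per_joint.items():
            cols[f"moment_arm_{m}_{j}"] = v
    pd.DataFrame(cols).to_csv(path / "timeseries.csv", index=False,
                              float_format="%.17g")
    emg_cols = {"time": dataset.emg_time}
    emg_cols.update(dataset.emg)
    pd.DataFrame(emg_cols).to_csv(path / "emg.csv", index=False,
                                  float_format="%.17g")
    ev = dataset.events
    (path / "events.json").write_text(json.dumps({
        "heel_strikes": ev.heel_strikes.tolist(),
        "toe_offs": ev.toe_offs.tolist(),
        "contra_heel_strikes": ev.contra_heel_strikes.tolist(),
        "contra_toe_offs": ev.contra_toe_offs.tolist(),
    }, indent=1))
    (path / "subject.json").write_text(json.dumps(asdict(dataset.scalars),
                                                  indent=1))
    return path


def read_dataset(path: str | Path) -> GaitDataset:
    """Read and validate a dataset directory.

    Raises a named error for a missing channel, a non-monotone clock, or
    an incomplete moment-arm table.
    """
    path = Path(path)
    for required in ("timeseries.csv", "emg.csv", "events.json", "subject.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"dataset at {path} is missing {required}")
    ts = pd.read_csv(path / "timeseries.csv", float_precision="round_trip")
    if "time" not in ts.columns:
        raise ValueError("timeseries.csv has no 'time' column")
    angles = {c[len("angle_"):]: ts[c].to_numpy()
              for c in ts.columns if c.startswith("angle_")}
    moments = {c[len("moment_"):]: ts[c].to_numpy()
               for c in ts.columns
               if c.startswith("moment_") and not c.startswith("moment_arm_")}
    lengths = {c[len("mtu_length_"):]: ts[c].to_numpy()
               for c in ts.columns if c.startswith("mtu_length_")}
    arms: dict[str, dict[str, np.ndarray]] = {}
    for c in ts.columns:
        if c.startswith("moment_arm_"):
            muscle, joint = c[len("moment_arm_"):].rsplit("_", 1)
            arms.setdefault(muscle, {})[joint] = ts[c].to_numpy()
    for m in lengths:
        if m not in arms or not arms[m]:
            raise ValueError(f"dataset is missing moment-arm channels for "
                             f"muscle {m!r}")
    emg_df = pd.read_csv(path / "emg.csv", float_precision="round_trip")
    emg_time = emg_df["time"].to_numpy()
    emg = {c: emg_df[c].to_numpy() for c in emg_df.columns if c != "time"}
    ev = json.loads((path / "events.json").read_text())
    events = GaitEvents(
        heel_strikes=np.asarray(ev["heel_strikes"], dtype=float),
        toe_offs=np.asarray(ev["toe_offs"], dtype=float),
        contra_heel_strikes=np.asarray(ev["contra_heel_strikes"], dtype=float),
        contra_toe_offs=np.asarray(ev["contra_toe_offs"], dtype=float))
    scalars = SubjectScalars(**json.loads((path / "subject.json").read_text()))
    return GaitDataset(time=ts["time"].to_numpy(), joint_angles=angles,
                       mtu_lengths=lengths, moment_arms=arms,
                       joint_moments=moments, emg_time=emg_time, emg=emg,
                       events=events, scalars=scalars)


def write_params(vector: MorphologyVector, path: str | Path) -> Path:
    """Write a morphology vector as a per-muscle JSON file."""
    path = Path(path)
    path.write_text(json.dumps(vector.to_dict(), indent=1))
    return path


def read_params(path: str | Path, validate: bool = True) -> MorphologyVector:
    """Read a per-muscle parameter JSON and optionally range-check it.

    Validation enforces the physical ranges of the tendon material
    parameters (K_sh in [2, 5], lambda_ref in [0.02, 0.09]) and
    positivity of strength and length scale, naming the offending field.
    """
    d = json.loads(Path(path).read_text())
    if validate:
        for muscle, block in d.items():
            if muscle == "HFL":
                if block.get("K_HFL", 0.0) < 0:
                    raise ValueError("HFL.K_HFL must be >= 0")
                continue
            for key, (lov, hiv) in _PARAM_RANGES.items():
                if key not in block:
                    raise ValueError(f"{muscle}: missing field {key!r}")
                v = float(block[key])
                if not (lov <= v <= hiv) or (key in ("F_max", "length_scale") and v <= 0):
                    raise ValueError(
                        f"{muscle}.{key}={v} outside valid range "
                        f"[{lov}, {hiv}]")
    return MorphologyVector.from_dict(d)


def load_participant(n: int) -> MorphologyVector:
    """Packaged optimal parameter fixture for participant n (1-5)."""
    if not 1 <= n <= 5:
        raise ValueError("participant index must be 1..5")
    with resources.files("gaitmtu.data").joinpath(f"participant{n}.json").open() as fh:
        return MorphologyVector.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline configuration

_CONFIG_KEYS = {
    "seed", "joints", "ga_preset", "moment_noise_rel",
    "sanger_alpha", "sanger_beta", "sanger_grid_size",
    "activation_threshold", "n_emg_cycles", "delta_vas_cutoff",
}


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run.

    Unknown keys in a config file are rejected; every run should echo the
    resolved configuration next to its outputs for provenance.
    """

    seed: int = 0
    joints: tuple[str, ...] = ("ankle", "knee", "hip")
    ga_preset: str = "desk"  # "desk" | "paper"
    moment_noise_rel: float = 0.02
    sanger_alpha: float = 0.5
    sanger_beta: float = 5e-31
    sanger_grid_size: int = 100
    activation_threshold: float = 0.05
    n_emg_cycles: int = 8
    delta_vas_cutoff: float = 0.63

    def __post_init__(self) -> None:
        if self.ga_preset not in ("desk", "paper"):
            raise ValueError("ga_preset must be 'desk' or 'paper'")
        self.joints = tuple(self.joints)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        d["joints"] = list(self.joints)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
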