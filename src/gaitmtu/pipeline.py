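"""High-level pipeline stages that chain the library modules.

These functions connect the EMG stage to the mechanics stage (drive
estimation, cycle averaging, resampling to the mechanics clock,
activation dynamics) and assemble the summary report for a parameter
set. They are what the command-line interface calls; library users can
equally call the underlying modules directly.
"""

from __future__ import annotations

import numpy as np

from . import emg as emg_mod
from . import energetics as en
from . import identify as ident
from . import mtu as mtu_mod
from .datatypes import GaitDataset, MorphologyVector
from .muscles import MUSCLES

__all__ = ["estimate_activations", "assemble_report"]


def estimate_activations(dataset: GaitDataset,
                         sanger_cfg: emg_mod.SangerConfig | None = None,
                         threshold: float = 0.05,
                         ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """EMG channels -> per-muscle (drive, activation) on the mechanics grid.

    Each channel is preprocessed, passed through the Bayesian drive
    filter, broken into gait cycles and robustly averaged onto the
    percent-gait-cycle grid, resampled to the mechanics clock, and shaped
    by the activation dynamics. Without MVC trials the absolute drive
    scale is unidentifiable; downstream identification absorbs it into
    F_max (each mean-cycle drive is left on the filter's own scale).
    """
    sanger_cfg = sanger_cfg or emg_mod.SangerConfig()
    emg_fs = 1.0 / float(dataset.emg_time[1] - dataset.emg_time[0])
    n_mech = dataset.time.size
    drives: dict[str, np.ndarray] = {}
    activations: dict[str, np.ndarray] = {}
    for m, raw in dataset.emg.items():
        rect = emg_mod.preprocess_emg(raw, fs=emg_fs)
        xhat = emg_mod.estimate_drive(rect, sanger_cfg)
        mean_cycle, _, _, _ = emg_mod.segment_and_average(
            dataset.emg_time, xhat, dataset.events, n_points=n_mech)
        mean_cycle = np.clip(mean_cycle, 0.0, 1.0)
        spec = MUSCLES[m]
        cfg = emg_mod.ActivationConfig(tau_act=spec.tau_act,
                                       tau_deact=spec.tau_deact,
                                       threshold=threshold)
        drives[m] = mean_cycle
        activations[m] = emg_mod.activation_dynamics(dataset.time,
                                                     mean_cycle, cfg)
    return drives, activations


def assemble_report(dataset: GaitDataset, vector: MorphologyVector,
                    activations: dict[str, np.ndarray],
                    drives: dict[str, np.ndarray] | None = None) -> dict:
    """Simulate a parameter set and compile moments, energetics, and
    muscle-state summaries into one plain dict (JSON-serializable)."""
    from .synthetic import params_from_vector

    params, hfl = params_from_vector(vector)
    traces, tau_mod = mtu_mod.simulate_leg(dataset, activations, params,
                                           hfl=hfl)
    c_kin, r2 = ident.kinetic_cost(tau_mod, dataset.joint_moments)
    mask = ident.stance_mask(dataset)
    fmae_per_joint = {j: ident.fmae(tau_mod[j], dataset.joint_moments[j], mask)
                      for j in tau_mod}
    u = drives if drives is not None else activations
    report = en.energetics_report(traces, u, activations, params,
                                  dataset.scalars, events=dataset.events)
    muscle_state = {
        m: {
            "l_ce_norm_mean": float(np.mean(tr.l_CE) / params[m].l_opt),
            "l_ce_norm_range": [float(tr.l_CE.min() / params[m].l_opt),
                                float(tr.l_CE.max() / params[m].l_opt)],
            "v_ce_over_vmax_range": [float(tr.v_CE.min() / params[m].v_max_abs),
                                     float(tr.v_CE.max() / params[m].v_max_abs)],
            "peak_force_N": float(tr.F_MTC.max()),
        }
        for m, tr in traces.items()
    }
    return {
        "mean_R2": 1.0 - c_kin,
        "C_kin": c_kin,
        "per_joint_R2": r2,
        "fmae": fmae_per_joint,
        "C_met_J": report.C_met,
        "mcot": report.mcot,
        "phase_fractions": {
            "double_support": report.phase_fractions[0],
            "single_support": report.phase_fractions[1],
            "swing": report.phase_fractions[2],
        },
        "positive_work_efficiency": report.positive_work_efficiency,
        "muscle_energy_J": report.muscle_energy,
        "muscle_state": muscle_state,
    }
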