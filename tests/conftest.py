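"""Shared fixtures: synthetic subjects at fixed seeds.

Session scope keeps the compiled simulation kernels and forward
generations shared across test modules.
"""

import pytest

from gaitmtu import synthetic as syn
from gaitmtu.synthetic import params_from_vector


@pytest.fixture(scope="session")
def full_subject():
    """12-muscle, 3-joint synthetic subject with default (2%) moment noise."""
    dataset, truth, bounds = syn.make_subject(seed=1)
    return dataset, truth, bounds


@pytest.fixture(scope="session")
def ankle_subject_noiseless():
    """3-muscle single-joint subject with zero moment noise (recovery oracle)."""
    dataset, truth, bounds = syn.make_subject(seed=3, joints=("ankle",),
                                              moment_noise_rel=0.0)
    return dataset, truth, bounds


@pytest.fixture(scope="session")
def full_truth_simulation(full_subject):
    """Truth morphology simulated on its own dataset (traces + moments)."""
    from gaitmtu import mtu as mtu_mod

    dataset, truth, _ = full_subject
    params, hfl = params_from_vector(truth.morphology)
    traces, tau = mtu_mod.simulate_leg(dataset, truth.activations, params,
                                       hfl=hfl)
    return dataset, truth, params, traces, tau
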