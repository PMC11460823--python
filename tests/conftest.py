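import numpy as np
import pytest

from arousalnet.params import (ArchitectureParams, ArousalModulation,
                               NeuronParams, SimConfig, default_config)
from arousalnet.network import build_clustered, build_uniform, make_stimulus_set
from arousalnet.simulate import run_experiment


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def small_arch():
    """A small clustered architecture with exactly integral subgroup counts
    (f = 1/6, p = 3; all f_b * C_ab integral)."""
    return ArchitectureParams(
        N_E=240, N_I=60, p=3, f_E=1 / 6, f_I=1 / 6,
        p_EE=0.2, p_EI=0.5, p_IE=0.5, p_II=0.5,
        J_EE=0.05, J_EI=-0.2, J_IE=0.05, J_II=-0.15,
        Jplus_EE=0.25, Jplus_EI=-0.24, Jplus_IE=0.06, Jplus_II=-0.18,
        C_ext_E=48, C_ext_I=48, J_ext_E=0.3, J_ext_I=0.18,
        nu_o_E=7.0, nu_o_I=7.0)


@pytest.fixture(scope="session")
def small_clustered(small_arch, neuron):
    return build_clustered(small_arch, neuron, seed=7)


@pytest.fixture(scope="session")
def small_uniform(small_arch, neuron):
    return build_uniform(small_arch, neuron, seed=7)


@pytest.fixture(scope="session")
def reduced_cfg():
    return default_config("reduced")


@pytest.fixture(scope="session")
def small_trialset(reduced_cfg):
    """A short evoked TrialSet from the reduced clustered network: 5 stimuli
    x 4 trials, 1.7 s trials with onset at 1 s."""
    arch, neuron = reduced_cfg["architecture"], reduced_cfg["neuron"]
    inst = build_clustered(arch, neuron, seed=11)
    stimuli = make_stimulus_set(inst, 5, seed=12, A_stim_E=0.07, t_stim=1.0)
    sc = SimConfig(dt=1e-4, trial_duration=1.7, t_stim=1.0,
                   n_trials_per_stimulus=4, seed=13)
    ts = run_experiment(inst, stimuli, sc)
    ts.instance = inst
    ts.stimuli = stimuli
    return ts
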