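"""Leaky integrate-and-fire network simulation.

The membrane and synaptic equations are linear between spikes, so each time
step advances them with their exact exponential propagators; threshold
crossings are detected on the grid and spike times are forced to the grid.
Background input arrives as an aggregate Poisson event stream per cell
(superposition of the independent external synapses), injected into the
excitatory synaptic variable with the external weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .network import NetworkInstance, stimulus_timecourse
from .params import ArousalModulation, SimConfig, StimulusSpec

__all__ = ["SpikeData", "TrialSet", "simulate_trial", "run_experiment",
           "simulate_single_neuron"]


@dataclass
class SpikeData:
    """Spikes of one simulated trial."""

    spikes: pd.DataFrame          # unit_id, time_s
    trial_id: int
    stimulus: Optional[int]       # None for spontaneous-only trials
    duration: float
    t_stim: float

    def as_frame(self) -> pd.DataFrame:
        df = self.spikes.copy()
        df["trial_id"] = self.trial_id
        df["stimulus"] = -1 if self.stimulus is None else self.stimulus
        df["epoch"] = np.where(df["time_s"] < self.t_stim, "spont", "evoked")
        return df


@dataclass
class TrialSet:
    """Spikes over trials x stimuli for one network realization and one
    arousal-modulation value."""

    spikes: pd.DataFrame          # unit_id, time_s, trial_id, stimulus, epoch
    unit_cluster: np.ndarray
    unit_pop: np.ndarray
    n_trials: int
    duration: float
    t_stim: float
    stimuli: list = field(default_factory=list)
    modulation: Optional[ArousalModulation] = None
    provenance: dict = field(default_factory=dict)

    @property
    def stimulus_ids(self) -> np.ndarray:
        s = np.unique(self.spikes["stimulus"].to_numpy())
        return s[s >= 0]

    def trials(self):
        """Iterate (trial_id, stimulus, unit_ids, times) per trial."""
        for (tid, stim), df in self.spikes.groupby(["trial_id", "stimulus"], sort=True):
            yield tid, stim, df["unit_id"].to_numpy(), df["time_s"].to_numpy()


@njit(cache=True)
def _lif_kernel(n_steps, dt, indptr, indices, weights, tau_m, v_th, v_r, n_ref,
                dE, dI, cE, cI, cS, ext_rate, ext_kick, stim_amp, stim_s,
                v0, seed, max_spikes):
    np.random.seed(seed)
    N = tau_m.shape[0]
    V = v0.copy()
    IE = np.zeros(N)
    II = np.zeros(N)
    refr = np.zeros(N, dtype=np.int64)
    dV = np.exp(-dt / tau_m)
    t_next = np.empty(N)
    for i in range(N):
        if ext_rate[i] > 0.0:
            t_next[i] = np.random.exponential(1.0 / ext_rate[i])
        else:
            t_next[i] = 1e18
    sp_t = np.empty(max_spikes, dtype=np.int64)
    sp_i = np.empty(max_spikes, dtype=np.int32)
    n_sp = 0
    spiked = np.empty(N, dtype=np.int32)
    for step in range(n_steps):
        t_end = (step + 1) * dt
        s_val = stim_s[step]
        n_now = 0
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = v_r[i]
            else:
                V[i] = (V[i] * dV[i] + IE[i] * cE[i] + II[i] * cI[i]
                        + stim_amp[i] * s_val * cS[i])
                if V[i] >= v_th[i]:
                    V[i] = v_r[i]
                    refr[i] = n_ref[i]
                    if n_sp >= max_spikes:
                        return sp_t, sp_i, -1, V
                    sp_t[n_sp] = step + 1
                    sp_i[n_sp] = i
                    n_sp += 1
                    spiked[n_now] = i
                    n_now += 1
            # decay synaptic state, then inject external events due this step
            IE[i] *= dE
            II[i] *= dI
            while t_next[i] <= t_end:
                IE[i] += ext_kick[i]
                t_next[i] += np.random.exponential(1.0 / ext_rate[i])
        for k in range(n_now):
            j = spiked[k]
            for q in range(indptr[j], indptr[j + 1]):
                w = weights[q]
                tgt = indices[q]
                if w >= 0.0:
                    IE[tgt] += w
                else:
                    II[tgt] += w
        if not np.isfinite(V[0]):
            return sp_t, sp_i, -2, V
    return sp_t, sp_i, n_sp, V


def _per_cell_arrays(instance: NetworkInstance, dt: float):
    n = instance.neuron
    pop = instance.pop_of
    tau_m = np.where(pop == 0, n.tau_m_E, n.tau_m_I)
    v_th = np.where(pop == 0, n.V_thresh_E, n.V_thresh_I)
    v_r = np.where(pop == 0, n.V_r_E, n.V_r_I)
    t_ref = np.where(pop == 0, n.tau_ref_E, n.tau_ref_I)
    n_ref = np.round(t_ref / dt).astype(np.int64)
    dE = np.exp(-dt / n.tau_syn_E)
    dI = np.exp(-dt / n.tau_syn_I)

    def prop(tau_s):
        return (np.exp(-dt / tau_s) - np.exp(-dt / tau_m)) / (1.0 / tau_m - 1.0 / tau_s)

    cE = prop(n.tau_syn_E)
    cI = prop(n.tau_syn_I)
    cS = tau_m * (1.0 - np.exp(-dt / tau_m))
    return tau_m, v_th, v_r, n_ref, dE, dI, cE, cI, cS


def simulate_trial(instance: NetworkInstance, nu_ext: np.ndarray,
                   stimulus: Optional[StimulusSpec], config: SimConfig,
                   trial_seed: int, trial_id: int = 0,
                   duration: Optional[float] = None) -> SpikeData:
    """Integrate one trial and return its spikes.

    ``nu_ext`` is the per-cell external rate (spikes/s per external synapse);
    the aggregate background rate per cell is ``C_ext * nu_ext``.
    """
    arch = instance.arch
    neuron = instance.neuron
    dt = config.dt
    T = config.trial_duration if duration is None else duration
    n_steps = int(round(T / dt))
    N = instance.N
    tau_m, v_th, v_r, n_ref, dE, dI, cE, cI, cS = _per_cell_arrays(instance, dt)

    W = instance.W
    # scale recurrent kicks: a spike adds J/tau_syn so its current integral is J
    kick_scale = np.where(W.data >= 0, 1.0 / neuron.tau_syn_E, 1.0 / neuron.tau_syn_I)
    weights = (W.data * kick_scale).astype(np.float64)

    C_ext = np.where(instance.pop_of == 0, arch.C_ext_E, arch.C_ext_I)
    ext_rate = (C_ext * np.asarray(nu_ext, dtype=float))
    J_ext = np.where(instance.pop_of == 0, arch.J_ext_E, arch.J_ext_I)
    ext_kick = J_ext / neuron.tau_syn_E

    stim_amp = np.zeros(N)
    stim_s = np.zeros(n_steps)
    if stimulus is not None:
        nu_o = arch.nu_o_E
        amp = stimulus.A_stim_E * nu_o * arch.C_ext_E * arch.J_ext_E
        stim_amp[stimulus.targeted_cells] = amp
        tgrid = (np.arange(n_steps) + 1) * dt
        stim_s = stimulus_timecourse(tgrid, stimulus.tau_r, stimulus.tau_d,
                                     t_stim=config.t_stim)

    rng = np.random.default_rng(trial_seed)
    v0 = v_r + rng.random(N) * (v_th - v_r)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    mean_rate_guess = 200.0
    max_spikes = int(N * T * mean_rate_guess) + 10000
    sp_t, sp_i, n_sp, V = _lif_kernel(
        n_steps, dt, W.indptr, W.indices, weights, tau_m, v_th, v_r, n_ref,
        dE, dI, cE, cI, cS, ext_rate, ext_kick, stim_amp, stim_s, v0,
        kernel_seed, max_spikes)
    if n_sp == -2 or not np.all(np.isfinite(V)):
        raise FloatingPointError("membrane potential diverged (non-finite voltage); "
                                 "check weights and dt")
    if n_sp == -1:
        raise RuntimeError("spike buffer overflow: network firing rate exceeds "
                           f"{mean_rate_guess} spikes/s per cell on average")
    df = pd.DataFrame({
        "unit_id": sp_i[:n_sp].astype(np.int32),
        "time_s": sp_t[:n_sp].astype(np.float64) * dt,
    })
    return SpikeData(spikes=df, trial_id=trial_id,
                     stimulus=None if stimulus is None else stimulus.stim_id,
                     duration=T, t_stim=config.t_stim)


def run_experiment(instance: NetworkInstance, stimuli: Sequence[StimulusSpec],
                   config: SimConfig, modulation: Optional[ArousalModulation] = None,
                   spontaneous_only: bool = False,
                   spontaneous_duration: float = 2.7,
                   n_spontaneous_trials: int = 30) -> TrialSet:
    """Simulate a block of trials for one network realization.

    With ``spontaneous_only`` the stimuli are ignored and
    ``n_spontaneous_trials`` unstimulated trials of ``spontaneous_duration``
    are run instead (used for spectral analyses). Otherwise
    ``config.n_trials_per_stimulus`` trials are simulated per stimulus.
    """
    if modulation is not None:
        from .network import assign_external_rates
        assign_external_rates(instance, modulation)
    nu_ext = instance.nu_ext
    rng = np.random.default_rng(config.seed)
    frames = []
    trial_id = 0
    if spontaneous_only:
        jobs = [(None, k) for k in range(n_spontaneous_trials)]
    else:
        jobs = [(s, k) for s in stimuli for k in range(config.n_trials_per_stimulus)]
    for stim, _k in jobs:
        seed = int(rng.integers(0, 2**31 - 1))
        sd = simulate_trial(instance, nu_ext, stim, config, trial_seed=seed,
                            trial_id=trial_id,
                            duration=spontaneous_duration if spontaneous_only else None)
        frames.append(sd.as_frame())
        trial_id += 1
    if frames:
        spikes = pd.concat(frames, ignore_index=True)
    else:
        spikes = pd.DataFrame(columns=["unit_id", "time_s", "trial_id",
                                       "stimulus", "epoch"])
    return TrialSet(spikes=spikes, unit_cluster=instance.cluster_of.copy(),
                    unit_pop=instance.pop_of.copy(),
                    n_trials=trial_id, duration=(spontaneous_duration if
                                                 spontaneous_only else config.trial_duration),
                    t_stim=config.t_stim, stimuli=list(stimuli) if not spontaneous_only else [],
                    modulation=modulation,
                    provenance=dict(seed=config.seed, dt=config.dt,
                                    network_seed=instance.seed))


def simulate_single_neuron(mu: float, sigma: float, neuron, alpha: str = "E",
                           duration: float = 100.0, dt: float = 0.5e-4,
                           seed: int = 0) -> float:
    """Firing rate of one LIF neuron driven by an external Poisson stream
    whose diffusion limit has mean ``mu`` and noise ``sigma`` (the synaptic
    weight J = sigma^2/mu and rate C*nu = mu^2/sigma^2 reproduce both moments).

    This is the simulation oracle for the mean-field transfer function.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0 to realize the input as an excitatory "
                         "Poisson stream")
    pp = neuron.pop(alpha)
    J = sigma ** 2 / mu
    rate = mu ** 2 / sigma ** 2
    n_steps = int(round(duration / dt))
    tau_m = np.array([pp["tau_m"]])
    v_th = np.array([pp["V_thresh"]])
    v_r = np.array([pp["V_r"]])
    n_ref = np.array([int(round(pp["tau_ref"] / dt))], dtype=np.int64)
    tau_sE, tau_sI = neuron.tau_syn_E, neuron.tau_syn_I
    dE, dI = np.exp(-dt / tau_sE), np.exp(-dt / tau_sI)
    cE = (np.exp(-dt / tau_sE) - np.exp(-dt / tau_m)) / (1 / tau_m - 1 / tau_sE)
    cI = (np.exp(-dt / tau_sI) - np.exp(-dt / tau_m)) / (1 / tau_m - 1 / tau_sI)
    cS = tau_m * (1 - np.exp(-dt / tau_m))
    indptr = np.zeros(2, dtype=np.int32)
    sp_t, sp_i, n_sp, V = _lif_kernel(
        n_steps, dt, indptr, np.zeros(0, np.int32), np.zeros(0),
        tau_m, v_th, v_r, n_ref, dE, dI, cE, cI, cS,
        np.array([rate]), np.array([J / tau_sE]), np.zeros(1), np.zeros(n_steps),
        np.array([v_r[0]]), seed, int(duration * 2000) + 100)
    if n_sp < 0:
        raise RuntimeError("single-neuron simulation failed")
    return n_sp / duration
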