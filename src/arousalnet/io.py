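"""HDF5 / tabular serialization of networks, trial sets and sessions."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .network import NetworkInstance
from .params import ArchitectureParams, NeuronParams
from .simulate import TrialSet

__all__ = ["save_network", "load_network", "save_trialset", "load_trialset",
           "save_session", "load_session_spikes"]


def save_network(path, inst: NetworkInstance):
    W = inst.W.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("weights/row", data=W.row.astype(np.int32))
        f.create_dataset("weights/col", data=W.col.astype(np.int32))
        f.create_dataset("weights/data", data=W.data)
        f.create_dataset("cluster_of", data=inst.cluster_of)
        f.create_dataset("pop_of", data=inst.pop_of)
        f.create_dataset("nu_ext", data=inst.nu_ext)
        f.attrs["seed"] = inst.seed
        f.attrs["clustered"] = inst.clustered
        f.attrs["N"] = inst.N
        f.attrs["arch"] = json.dumps(asdict(inst.arch))
        f.attrs["neuron"] = json.dumps(asdict(inst.neuron))


def load_network(path) -> NetworkInstance:
    with h5py.File(path, "r") as f:
        N = int(f.attrs["N"])
        W = sparse.csc_matrix(
            (f["weights/data"][:], (f["weights/row"][:], f["weights/col"][:])),
            shape=(N, N))
        inst = NetworkInstance(
            W=W, cluster_of=f["cluster_of"][:], pop_of=f["pop_of"][:],
            nu_ext=f["nu_ext"][:],
            arch=ArchitectureParams(**json.loads(f.attrs["arch"])),
            neuron=NeuronParams(**json.loads(f.attrs["neuron"])),
            seed=int(f.attrs["seed"]), clustered=bool(f.attrs["clustered"]))
    return inst


def save_trialset(path, ts: TrialSet):
    """Columnar spike table plus unit metadata in one HDF5 container."""
    with h5py.File(path, "w") as f:
        for col in ("unit_id", "trial_id", "stimulus"):
            f.create_dataset(f"spikes/{col}", data=ts.spikes[col].to_numpy(np.int32))
        f.create_dataset("spikes/time_s", data=ts.spikes["time_s"].to_numpy())
        f.create_dataset("unit_cluster", data=ts.unit_cluster)
        f.create_dataset("unit_pop", data=ts.unit_pop)
        f.attrs["n_trials"] = ts.n_trials
        f.attrs["duration"] = ts.duration
        f.attrs["t_stim"] = ts.t_stim
        f.attrs["provenance"] = json.dumps(ts.provenance)


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        df = pd.DataFrame({c: f[f"spikes/{c}"][:]
                           for c in ("unit_id", "time_s", "trial_id", "stimulus")})
        df = df.astype({"unit_id": np.int32, "trial_id": np.int64,
                        "stimulus": np.int64})
        df["epoch"] = np.where(df["time_s"] < f.attrs["t_stim"], "spont", "evoked")
        return TrialSet(spikes=df, unit_cluster=f["unit_cluster"][:],
                        unit_pop=f["unit_pop"][:], n_trials=int(f.attrs["n_trials"]),
                        duration=float(f.attrs["duration"]),
                        t_stim=float(f.attrs["t_stim"]),
                        provenance=json.loads(f.attrs["provenance"]))


def save_session(path, session):
    """Spikes, pupil, running, events and amplitudes of a synthetic session."""
    with h5py.File(path, "w") as f:
        for u, st in enumerate(session.spikes):
            f.create_dataset(f"spikes/{u}", data=st)
        for u, (at, av) in enumerate(session.amplitudes):
            f.create_dataset(f"amplitudes/{u}/time", data=at)
            f.create_dataset(f"amplitudes/{u}/amp", data=av)
        f.create_dataset("pupil/diameter", data=session.pupil.diameter)
        f.create_dataset("pupil/valid", data=session.pupil.valid)
        f.create_dataset("running", data=session.running)
        f.create_dataset("events/time", data=session.events["time"].to_numpy())
        f.create_dataset("events/stim_id",
                         data=session.events["stim_id"].to_numpy(np.int32))
        f.attrs["duration"] = session.duration
        f.attrs["seed"] = session.seed
        f.attrs["blocks"] = json.dumps([(a, b, k) for a, b, k in session.blocks])


def load_session_spikes(path):
    """Load just the per-unit spike trains of a saved session."""
    with h5py.File(path, "r") as f:
        n = len(f["spikes"])
        return [f[f"spikes/{u}"][:] for u in range(n)]
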