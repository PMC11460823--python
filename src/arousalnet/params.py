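"""Parameter containers for the clustered E/I spiking-network model.

Conventions
-----------
* All times are in seconds, all rates in spikes/s.
* Membrane potentials are dimensionless (threshold order 1); synaptic weights
  are voltage jump sizes in the same units, scaled ~ 1/sqrt(N) in the shipped
  configs so that networks of different size sit in comparable regimes.
* Inhibitory weights (``J_EI``, ``J_II`` and their intracluster counterparts)
  are stored as *signed* (negative) numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "ArchitectureParams",
    "ArousalModulation",
    "StimulusSpec",
    "SimConfig",
    "load_config",
    "default_config",
]


@dataclass
class NeuronParams:
    """Intrinsic parameters of the leaky integrate-and-fire populations."""

    tau_m_E: float = 20e-3
    tau_m_I: float = 20e-3
    V_thresh_E: float = 1.5
    V_thresh_I: float = 0.75
    V_r_E: float = 0.0
    V_r_I: float = 0.0
    tau_ref_E: float = 5e-3
    tau_ref_I: float = 5e-3
    tau_syn_E: float = 4e-3
    tau_syn_I: float = 4e-3

    def __post_init__(self):
        for name in ("tau_m_E", "tau_m_I", "tau_syn_E", "tau_syn_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tau_ref_E", "tau_ref_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.V_r_E >= self.V_thresh_E or self.V_r_I >= self.V_thresh_I:
            raise ValueError("reset potential must lie below threshold")

    def pop(self, alpha: str) -> dict:
        """Return the scalar parameters of population ``alpha`` in {'E','I'}."""
        a = alpha.upper()
        return dict(
            tau_m=getattr(self, f"tau_m_{a}"),
            V_thresh=getattr(self, f"V_thresh_{a}"),
            V_r=getattr(self, f"V_r_{a}"),
            tau_ref=getattr(self, f"tau_ref_{a}"),
        )


@dataclass
class ArchitectureParams:
    """Sizes, connectivity and synaptic weights of the recurrent circuit.

    ``Jplus_ab`` are the within-cluster weights; the depressed between-cluster
    weights follow from weight-sum conservation (see
    :func:`arousalnet.network.depressed_intercluster_weight`).
    """

    N_E: int = 1600
    N_I: int = 400
    p: int = 18
    f_E: float = 0.05
    f_I: float = 0.05
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    J_EE: float = 0.0
    J_EI: float = 0.0
    J_IE: float = 0.0
    J_II: float = 0.0
    Jplus_EE: float = 0.0
    Jplus_EI: float = 0.0
    Jplus_IE: float = 0.0
    Jplus_II: float = 0.0
    C_ext_E: int = 0
    C_ext_I: int = 0
    J_ext_E: float = 0.0
    J_ext_I: float = 0.0
    nu_o_E: float = 7.0
    nu_o_I: float = 7.0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")
        for a in ("E", "I"):
            f = getattr(self, f"f_{a}")
            if not (0 < f) or self.p * f > 1 + 1e-12:
                raise ValueError(f"require 0 < f_{a} and p*f_{a} <= 1")
        if self.Jplus_EE < self.J_EE:
            raise ValueError("Jplus_EE must be >= J_EE")
        if self.J_EI > 0 or self.J_II > 0:
            raise ValueError("inhibitory weights must be <= 0 (signed convention)")
        for a in ("E", "I"):
            for b in ("E", "I"):
                C = getattr(self, f"p_{a}{b}") * getattr(self, f"N_{b}")
                if abs(C - round(C)) > 1e-9:
                    raise ValueError(f"C_{a}{b} = p_{a}{b}*N_{b} must be an integer")
        for a in ("E", "I"):
            C = getattr(self, f"C_ext_{a}")
            if C < 0:
                raise ValueError("external in-degrees must be >= 0")

    # -- derived in-degrees -------------------------------------------------
    def C(self, a: str, b: str) -> int:
        """Recurrent in-degree: number of type-``b`` inputs to a type-``a`` cell."""
        return int(round(getattr(self, f"p_{a.upper()}{b.upper()}") * getattr(self, f"N_{b.upper()}")))

    def J(self, a: str, b: str) -> float:
        return getattr(self, f"J_{a.upper()}{b.upper()}")

    def Jplus(self, a: str, b: str) -> float:
        return getattr(self, f"Jplus_{a.upper()}{b.upper()}")

    def f(self, a: str) -> float:
        return getattr(self, f"f_{a.upper()}")


@dataclass
class ArousalModulation:
    """Background-input modulation emulating a change in arousal.

    ``kind='mean'`` shifts every cell's external rate up by ``dM`` (relative);
    ``kind='heterogeneity'`` draws a quenched per-cell offset ``z*dH`` (z
    standard normal, fixed per network realization) so the population mean is
    preserved while the spread grows.
    """

    kind: str = "heterogeneity"
    dH_E: float = 0.0
    dH_I: float = 0.0
    dM_E: float = 0.0
    dM_I: float = 0.0
    seed: Optional[int] = None
    z: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("heterogeneity", "mean"):
            raise ValueError("kind must be 'heterogeneity' or 'mean'")
        for name in ("dH_E", "dH_I", "dM_E", "dM_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StimulusSpec:
    """One sensory stimulus: which cells it targets and its input waveform."""

    stim_id: int
    targeted_clusters: np.ndarray
    targeted_cells: np.ndarray
    A_stim_E: float = 0.10
    tau_r: float = 0.05
    tau_d: float = 0.15
    t_stim: float = 1.0

    def __post_init__(self):
        if self.tau_d <= self.tau_r or self.tau_r <= 0:
            raise ValueError("require tau_d > tau_r > 0")
        self.targeted_clusters = np.asarray(self.targeted_clusters, dtype=np.int64)
        self.targeted_cells = np.asarray(self.targeted_cells, dtype=np.int64)


@dataclass
class SimConfig:
    """Integration and trial-structure settings for the LIF simulator."""

    dt: float = 0.5e-4
    trial_duration: float = 3.5
    t_stim: float = 1.0
    n_trials_per_stimulus: int = 30
    record_voltage: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.t_stim <= self.trial_duration):
            raise ValueError("t_stim must lie inside the trial")


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def _arch_from_dict(d: dict) -> ArchitectureParams:
    """Build ArchitectureParams from a config dict.

    The config stores positive weight magnitudes ``j_ab`` (in units where the
    actual weight is j/sqrt(N)) and intracluster potentiation *factors*
    ``jplus_factor_ab`` >= 1; inhibitory signs are applied here.
    """
    N = d["N_E"] + d["N_I"]
    s = 1.0 / np.sqrt(N)
    J_EE = d["j_EE"] * s
    J_IE = d["j_IE"] * s
    J_EI = -d["j_EI"] * s
    J_II = -d["j_II"] * s
    return ArchitectureParams(
        N_E=d["N_E"],
        N_I=d["N_I"],
        p=d["p"],
        f_E=d["f_E"],
        f_I=d["f_I"],
        p_EE=d["p_EE"],
        p_EI=d["p_EI"],
        p_IE=d["p_IE"],
        p_II=d["p_II"],
        J_EE=J_EE,
        J_EI=J_EI,
        J_IE=J_IE,
        J_II=J_II,
        Jplus_EE=d["jplus_factor_EE"] * J_EE,
        Jplus_EI=d["jplus_factor_EI"] * J_EI,
        Jplus_IE=d["jplus_factor_IE"] * J_IE,
        Jplus_II=d["jplus_factor_II"] * J_II,
        C_ext_E=d["C_ext_E"],
        C_ext_I=d["C_ext_I"],
        J_ext_E=d["j_ext_E"] * s,
        J_ext_I=d["j_ext_I"] * s,
        nu_o_E=d["nu_o_E"],
        nu_o_I=d["nu_o_I"],
    )


def load_config(path_or_dict) -> dict:
    """Load a model config (YAML path or pre-parsed dict) into dataclasses.

    Returns a dict with keys ``neuron``, ``architecture``, ``arousal``,
    ``stimulus``, ``simulation``, ``raw``.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    neuron = NeuronParams(**raw.get("neuron", {}))
    arch = _arch_from_dict(raw["architecture"])
    arousal = ArousalModulation(**raw.get("arousal", {}))
    stim = dict(raw.get("stimulus", {}))
    sim = SimConfig(**raw.get("simulation", {}))
    return dict(neuron=neuron, architecture=arch, arousal=arousal,
                stimulus=stim, simulation=sim, raw=raw)


def default_config(name: str = "default") -> dict:
    """Load one of the shipped configs: ``default`` (full-size network whose
    intracluster E-to-E coupling factor is 15.75) or ``reduced`` (a smaller
    network used for fast sweeps)."""
    ref = resources.files("arousalnet.data").joinpath(f"{name}.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return load_config(raw)
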