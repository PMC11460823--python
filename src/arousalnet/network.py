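"""Construction of uniform and clustered E/I circuits.

Cells are indexed 0..N_E-1 (excitatory) then N_E..N-1 (inhibitory). Cluster
labels run 0..p-1 with ``p`` denoting the unclustered background group. The
weight matrix ``W`` is stored sparse with W[i, j] the (signed) strength of the
synapse from presynaptic cell j onto postsynaptic cell i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

from .params import ArchitectureParams, ArousalModulation, NeuronParams, StimulusSpec

__all__ = [
    "depressed_intercluster_weight",
    "random_conserving_architecture",
    "NetworkInstance",
    "build_uniform",
    "build_clustered",
    "assign_external_rates",
    "make_stimulus_set",
    "stimulus_timecourse",
    "stimulus_current",
]


def depressed_intercluster_weight(J_ab: float, Jplus_ab: float, f_a: float,
                                  f_b: float, p: int) -> float:
    """Between-cluster weight that conserves the total summed synaptic weight
    of the clustered network relative to the uniform one, given the baseline
    weight ``J_ab`` and the within-cluster weight ``Jplus_ab``."""
    denom = f_a + f_b - p * f_a * f_b - f_a * f_b
    if abs(denom) < 1e-15:
        raise ValueError("degenerate cluster fractions: weight-conservation "
                         "denominator vanishes")
    return ((f_a + f_b - p * f_a * f_b) * J_ab - f_a * f_b * Jplus_ab) / denom


def random_conserving_architecture(rng: np.random.Generator) -> ArchitectureParams:
    """Random small architecture from the family where all per-class in-degree
    counts are integers (f_a = 1/q_a and C_ab a multiple of q_b), so that
    weight-sum conservation between the uniform and clustered instances is
    exact rather than limited by in-degree rounding."""
    q_E = int(rng.integers(5, 9))
    q_I = int(rng.integers(5, 9))
    p = int(rng.integers(2, min(q_E, q_I)))
    m_E = int(rng.integers(8, 16))
    m_I = int(rng.integers(6, 10))
    N_E, N_I = m_E * q_E, m_I * q_I
    C = {}
    for a in ("E", "I"):
        for b, q_b, N_b in (("E", q_E, N_E), ("I", q_I, N_I)):
            C[a + b] = q_b * int(rng.integers(1, max(2, N_b // (2 * q_b))))
    J_EE = rng.uniform(0.05, 0.3)
    J_IE = rng.uniform(0.05, 0.3)
    jp = rng.uniform(1.0, 2.5)
    return ArchitectureParams(
        N_E=N_E, N_I=N_I, p=p, f_E=1.0 / q_E, f_I=1.0 / q_I,
        p_EE=C["EE"] / N_E, p_EI=C["EI"] / N_I,
        p_IE=C["IE"] / N_E, p_II=C["II"] / N_I,
        J_EE=J_EE, J_EI=-rng.uniform(0.1, 0.5), J_IE=J_IE,
        J_II=-rng.uniform(0.1, 0.5),
        Jplus_EE=jp * J_EE, Jplus_EI=-rng.uniform(0.5, 0.8),
        Jplus_IE=jp * J_IE, Jplus_II=-rng.uniform(0.5, 0.8),
        C_ext_E=10, C_ext_I=10, J_ext_E=0.1, J_ext_I=0.1)


@dataclass
class NetworkInstance:
    """A realized circuit: weights, assignments and external drive."""

    W: sparse.csc_matrix
    cluster_of: np.ndarray
    pop_of: np.ndarray           # 0 = E, 1 = I
    nu_ext: np.ndarray
    arch: ArchitectureParams
    neuron: NeuronParams
    seed: int
    clustered: bool

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def e_cells(self) -> np.ndarray:
        return np.flatnonzero(self.pop_of == 0)

    @property
    def i_cells(self) -> np.ndarray:
        return np.flatnonzero(self.pop_of == 1)

    def cluster_members(self, c: int, pop: str = "E") -> np.ndarray:
        mask = (self.cluster_of == c) & (self.pop_of == (0 if pop == "E" else 1))
        return np.flatnonzero(mask)


def _largest_remainder_counts(exact: np.ndarray, total: int) -> np.ndarray:
    """Round class counts to integers that sum exactly to ``total``
    (largest-remainder method; deterministic)."""
    floors = np.floor(exact).astype(int)
    rem = exact - floors
    missing = total - floors.sum()
    if missing < 0:
        order = np.argsort(rem)  # take away from smallest remainders
        for k in order[: -missing]:
            floors[k] -= 1
    elif missing > 0:
        order = np.argsort(-rem)
        for k in order[:missing]:
            floors[k] += 1
    if (floors < 0).any():
        raise ValueError("infeasible in-degree partition")
    return floors


def _check_feasible(arch: ArchitectureParams):
    for a in ("E", "I"):
        for b in ("E", "I"):
            if arch.C(a, b) > getattr(arch, f"N_{b}"):
                raise ValueError(f"in-degree C_{a}{b} exceeds N_{b}")


def build_uniform(arch: ArchitectureParams, neuron: NeuronParams, seed: int) -> NetworkInstance:
    """Uniform (unstructured) network: every type-a cell receives exactly
    C_ab randomly chosen type-b inputs of weight J_ab."""
    _check_feasible(arch)
    rng = np.random.default_rng(seed)
    N_E, N_I = arch.N_E, arch.N_I
    N = N_E + N_I
    pop_of = np.concatenate([np.zeros(N_E, np.int8), np.ones(N_I, np.int8)])
    pools = {"E": np.arange(N_E), "I": np.arange(N_E, N)}
    rows, cols, data = [], [], []
    for a, post_ids in (("E", pools["E"]), ("I", pools["I"])):
        for b in ("E", "I"):
            C = arch.C(a, b)
            J = arch.J(a, b)
            pool = pools[b]
            for i in post_ids:
                avail = pool[pool != i] if a == b else pool
                pre = rng.choice(avail, size=C, replace=False)
                rows.append(np.full(C, i, dtype=np.int32))
                cols.append(pre.astype(np.int32))
                data.append(np.full(C, J))
    W = sparse.csc_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N))
    cluster_of = np.full(N, arch.p, dtype=np.int32)  # all background
    nu_ext = np.where(pop_of == 0, arch.nu_o_E, arch.nu_o_I).astype(float)
    return NetworkInstance(W=W, cluster_of=cluster_of, pop_of=pop_of, nu_ext=nu_ext,
                           arch=arch, neuron=neuron, seed=seed, clustered=False)


def build_clustered(arch: ArchitectureParams, neuron: NeuronParams, seed: int) -> NetworkInstance:
    """Clustered network: f_a*N_a cells per cluster and type, potentiated
    within-cluster weights, depressed between-cluster and cluster/background
    weights, and in-degrees that sum exactly to C_ab per cell."""
    _check_feasible(arch)
    rng = np.random.default_rng(seed)
    N_E, N_I = arch.N_E, arch.N_I
    N = N_E + N_I
    p = arch.p
    pop_of = np.concatenate([np.zeros(N_E, np.int8), np.ones(N_I, np.int8)])

    cluster_of = np.full(N, p, dtype=np.int32)
    slot_of = np.full(N, -1, dtype=np.int32)
    members: dict = {}
    for a, n_a, offset in (("E", N_E, 0), ("I", N_I, N_E)):
        m = int(round(arch.f(a) * n_a))
        perm = rng.permutation(n_a) + offset
        for c in range(p):
            ids = perm[c * m:(c + 1) * m]
            cluster_of[ids] = c
            slot_of[ids] = np.arange(m)
            members[(a, c)] = np.sort(ids)
        members[(a, p)] = np.sort(perm[p * m:])

    rows, cols, data = [], [], []
    for a in ("E", "I"):
        post_all = members_all = np.flatnonzero(pop_of == (0 if a == "E" else 1))
        for b in ("E", "I"):
            C = arch.C(a, b)
            f_b = arch.f(b)
            J = arch.J(a, b)
            Jp = arch.Jplus(a, b)
            Jm = depressed_intercluster_weight(J, Jp, arch.f(a), f_b, p)
            other_pool = {c: np.concatenate([members[(b, l)] for l in range(p) if l != c])
                          for c in range(p)}
            all_clustered = np.concatenate([members[(b, l)] for l in range(p)])
            bg_pool = members[(b, p)]
            for i in post_all:
                g = cluster_of[i]
                if g < p:
                    exact = np.array([f_b * C, (p - 1) * f_b * C, (1 - p * f_b) * C])
                    n_same, n_other, n_bg = _largest_remainder_counts(exact, C)
                    pool_same = members[(b, g)]
                    if a == b:
                        pool_same = pool_same[pool_same != i]
                    pre_s = rng.choice(pool_same, size=n_same, replace=False)
                    pre_o = rng.choice(other_pool[g], size=n_other, replace=False)
                    pre_b = rng.choice(bg_pool, size=n_bg, replace=False)
                    pres = [pre_s, pre_o, pre_b]
                    ws = [Jp, Jm, Jm]
                else:
                    exact = np.array([p * f_b * C, (1 - p * f_b) * C])
                    n_cl, n_bg = _largest_remainder_counts(exact, C)
                    pre_c = rng.choice(all_clustered, size=n_cl, replace=False)
                    avail_bg = bg_pool[bg_pool != i] if a == b else bg_pool
                    pre_b = rng.choice(avail_bg, size=n_bg, replace=False)
                    pres = [pre_c, pre_b]
                    ws = [Jm, J]
                for pre, wgt in zip(pres, ws):
                    if len(pre) == 0:
                        continue
                    rows.append(np.full(len(pre), i, dtype=np.int32))
                    cols.append(pre.astype(np.int32))
                    data.append(np.full(len(pre), wgt))
    W = sparse.csc_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N))
    nu_ext = np.where(pop_of == 0, arch.nu_o_E, arch.nu_o_I).astype(float)
    inst = NetworkInstance(W=W, cluster_of=cluster_of, pop_of=pop_of, nu_ext=nu_ext,
                           arch=arch, neuron=neuron, seed=seed, clustered=True)
    inst.slot_of = slot_of  # within-cluster cell slot, used for shared disorder
    return inst


def assign_external_rates(instance: NetworkInstance, modulation: ArousalModulation,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-cell background input rates under an arousal modulation.

    ``mean``: nu_ext = nu_o * (1 + dM).  ``heterogeneity``: nu_ext =
    nu_o * (1 + z * dH) truncated at zero, with one standard-normal draw per
    within-cluster cell slot shared across all clusters (every cluster sees
    the same realization of the input distribution) and independent draws for
    background cells.  Updates ``instance.nu_ext`` in place and returns it.
    """
    arch = instance.arch
    N = instance.N
    nu_o = np.where(instance.pop_of == 0, arch.nu_o_E, arch.nu_o_I).astype(float)
    if modulation.kind == "mean":
        dM = np.where(instance.pop_of == 0, modulation.dM_E, modulation.dM_I)
        nu = nu_o * (1.0 + dM)
    else:
        if modulation.z is not None:
            z = np.asarray(modulation.z, dtype=float)
            if z.shape != (N,):
                raise ValueError("modulation.z must have one entry per cell")
        else:
            if rng is None:
                rng = np.random.default_rng(modulation.seed)
            z = np.empty(N)
            if instance.clustered:
                slot = instance.slot_of
                for a, code in (("E", 0), ("I", 1)):
                    sel = instance.pop_of == code
                    clustered_sel = sel & (instance.cluster_of < arch.p)
                    m = int(round(arch.f(a) * (arch.N_E if a == "E" else arch.N_I)))
                    z_slot = rng.standard_normal(m)
                    z[clustered_sel] = z_slot[slot[clustered_sel]]
                    bg_sel = sel & (instance.cluster_of == arch.p)
                    z[bg_sel] = rng.standard_normal(bg_sel.sum())
            else:
                z[:] = rng.standard_normal(N)
            modulation.z = z
        dH = np.where(instance.pop_of == 0, modulation.dH_E, modulation.dH_I)
        nu = np.maximum(nu_o * (1.0 + z * dH), 0.0)
    instance.nu_ext = nu
    return nu


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def stimulus_timecourse(t, tau_r: float, tau_d: float, t_stim: float = 0.0):
    """Peak-normalized difference of exponentials s(t); 0 before onset."""
    if tau_d <= tau_r or tau_r <= 0:
        raise ValueError("require tau_d > tau_r > 0")
    r = tau_r / tau_d
    gamma = 1.0 / (r ** (tau_r / (tau_d - tau_r)) - r ** (tau_d / (tau_d - tau_r)))
    t = np.asarray(t, dtype=float)
    u = t - t_stim
    s = gamma * (np.exp(-u / tau_d) - np.exp(-u / tau_r))
    return np.where(u >= 0, s, 0.0)


def stimulus_current(t, spec: StimulusSpec, nu_o: float, C_ext: int, J_ext: float):
    """Stimulus input current at time ``t`` for a targeted E cell (inhibitory
    cells receive no sensory drive; pass A=0 or use targeting masks)."""
    s = stimulus_timecourse(t, spec.tau_r, spec.tau_d, spec.t_stim)
    return spec.A_stim_E * nu_o * C_ext * J_ext * s


def make_stimulus_set(instance: NetworkInstance, n_stimuli: int = 5,
                      frac_clusters: float = 0.5, frac_cells: float = 0.5,
                      seed: int = 0, A_stim_E: float = 0.10, tau_r: float = 0.05,
                      tau_d: float = 0.15, t_stim: float = 1.0) -> list:
    """Random stimulus set: each stimulus targets ``frac_clusters`` of the
    clusters and ``frac_cells`` of the E cells within each targeted cluster
    (for a uniform network, a random E subset of matched total size)."""
    for name, frac in (("frac_clusters", frac_clusters), ("frac_cells", frac_cells)):
        if not (0 < frac <= 1):
            raise ValueError(f"{name} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    arch = instance.arch
    p = arch.p
    m_E = int(round(arch.f_E * arch.N_E))
    n_clus = max(1, int(round(frac_clusters * p)))
    n_per = max(1, int(round(frac_cells * m_E)))
    specs = []
    for sid in range(n_stimuli):
        if instance.clustered:
            clus = np.sort(rng.choice(p, size=n_clus, replace=False))
            cells = []
            for c in clus:
                mem = instance.cluster_members(int(c), "E")
                cells.append(rng.choice(mem, size=n_per, replace=False))
            cells = np.sort(np.concatenate(cells))
        else:
            clus = np.empty(0, dtype=np.int64)
            cells = np.sort(rng.choice(instance.e_cells, size=n_clus * n_per,
                                       replace=False))
        specs.append(StimulusSpec(stim_id=sid, targeted_clusters=clus,
                                  targeted_cells=cells, A_stim_E=A_stim_E,
                                  tau_r=tau_r, tau_d=tau_d, t_stim=t_stim))
    return specs
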