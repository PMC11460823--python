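"""Mean-field theory of clustered E/I LIF networks.

The theory describes each population (p excitatory clusters, p inhibitory
clusters, one E and one I background population) by a stationary firing rate
that solves ``nu = Phi(mu(nu), sigma(nu))``, where ``Phi`` is the first-passage
rate of an LIF neuron driven by white noise with a synaptic-filter correction
to the integration bounds, and the input mean/variance are linear in the
population rates with coefficients set by the connectivity.

Three levels are implemented:

* :func:`solve_mft` — homogeneous populations (no quenched disorder);
* :func:`solve_quenched_mft` — Gaussian quenched disorder of the background
  input (the "input heterogeneity" arousal modulation), which induces a
  distribution of rates within each population, handled by parameterizing the
  rate of a cell by its disorder variable z and closing the system on the
  population mean and spatial variance of the rates;
* :func:`effective_flow_map` / :func:`effective_potential` — a reduced network
  with two E clusters whose rates are frozen while the unclustered background
  populations adapt, yielding a 2D flow map, its fixed points, and a 1D
  effective potential whose barrier height controls switching between the two
  cluster attractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy.special import erfcx, erfi

from .params import ArchitectureParams, NeuronParams

__all__ = [
    "transfer_rate",
    "MeanFieldModel",
    "MFTSolution",
    "InputMoments",
    "mft_input_moments",
    "solve_mft",
    "solve_quenched_mft",
    "ReducedArchitecture",
    "default_reduced_architecture",
    "FlowMap",
    "EffectivePotential",
    "effective_flow_map",
    "effective_potential",
    "match_intracluster_coupling",
]

#: synaptic-correction constant -zeta(1/2)/2 for the integration bounds
A_SYN = 0.730177254404793

_GL_NODES, _GL_WEIGHTS = leggauss(100)
_Q_MAX = 26.0  # exp(q^2) overflows just above this; the rate is ~0 long before


def _gl_integral(func, lo, hi):
    """Elementwise Gauss-Legendre integral of a smooth bounded ``func`` over
    [lo, hi]; intervals with hi <= lo contribute 0."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    half = 0.5 * np.maximum(hi - lo, 0.0)
    mid = 0.5 * (hi + lo)
    x = mid[..., None] + half[..., None] * _GL_NODES
    return half * np.einsum("...k,k->...", func(x), _GL_WEIGHTS)


def _integral_exp_erfc(a, b):
    """Elementwise  I = int_a^b exp(x^2) erfc(-x) dx  (requires b >= a).

    Stable evaluation: for x < 0 the integrand equals erfcx(-x) (bounded); for
    x > 0 it equals 2 exp(x^2) - erfcx(x), whose divergent part integrates to
    sqrt(pi) * (erfi(b) - erfi(a)).  Values with b above ~26 overflow to inf,
    which maps to a rate of zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(np.broadcast(a, b).shape)
    # negative-axis piece
    neg_hi = np.minimum(b, 0.0)
    out += _gl_integral(lambda x: erfcx(-x), a, neg_hi)
    # positive-axis piece
    pos_lo = np.maximum(a, 0.0)
    with np.errstate(over="ignore"):
        gauss = np.sqrt(np.pi) * (erfi(np.minimum(b, _Q_MAX + 1)) - erfi(np.minimum(pos_lo, _Q_MAX + 1)))
    gauss = np.where(b > pos_lo, gauss, 0.0)
    big = b >= _Q_MAX
    gauss = np.where(big, np.inf, gauss)
    out += gauss - _gl_integral(erfcx, pos_lo, np.maximum(b, pos_lo))
    return out


def _phi(mu, sigma, tau_m, tau_s, tau_ref, V_r, V_th):
    """Vectorized LIF transfer function (spikes/s)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    corr = A_SYN * np.sqrt(tau_s / tau_m)
    denom = np.sqrt(tau_m) * sigma
    qr = (V_r - tau_m * mu) / denom + corr
    qt = (V_th - tau_m * mu) / denom + corr
    integral = _integral_exp_erfc(qr, qt)
    with np.errstate(divide="ignore"):
        rate = 1.0 / (tau_ref + tau_m * np.sqrt(np.pi) * integral)
    return np.where(np.isfinite(integral), rate, 0.0)


def transfer_rate(mu, sigma, neuron: NeuronParams, alpha: str = "E"):
    """Stationary firing rate of an LIF neuron of population ``alpha`` driven
    by Gaussian input with mean ``mu`` and noise amplitude ``sigma``.

    ``mu`` has units such that ``tau_m * mu`` is the mean voltage drive;
    ``sigma**2`` is the white-noise intensity (``tau_m * sigma**2`` is the
    free-membrane voltage variance scale). Accepts arrays.
    """
    pp = neuron.pop(alpha)
    tau_s = 0.5 * (neuron.tau_syn_E + neuron.tau_syn_I)
    return _phi(mu, sigma, pp["tau_m"], tau_s, pp["tau_ref"], pp["V_r"], pp["V_thresh"])


# ---------------------------------------------------------------------------
# population-level model
# ---------------------------------------------------------------------------


@dataclass
class InputMoments:
    """Input statistics per population: mean ``mu`` (or population-average
    ``mu`` when quenched), noise ``sigma``, and quenched spread ``delta``."""

    mu: np.ndarray
    sigma: np.ndarray
    delta: Optional[np.ndarray] = None
    quenched: bool = False


@dataclass
class MFTSolution:
    """Self-consistent population rates.

    ``rates`` is ordered [E cluster 1..p, E background, I cluster 1..p,
    I background]; for the quenched theory ``rates`` holds the population
    means and ``s2`` the spatial rate variances.
    """

    nA: int
    rates: np.ndarray
    residual: float
    converged: bool
    state_kind: str
    p: int
    s2: Optional[np.ndarray] = None

    @property
    def e_cluster_rates(self) -> np.ndarray:
        return self.rates[: self.p]

    @property
    def nu_up(self) -> float:
        e = self.e_cluster_rates
        if self.state_kind != "cluster_state":
            return float("nan")
        return float(e[: self.nA].mean())

    @property
    def nu_down(self) -> float:
        e = self.e_cluster_rates
        if self.state_kind != "cluster_state" or self.nA >= self.p:
            return float("nan")
        return float(e[self.nA:].mean())


class MeanFieldModel:
    """Linear input-moment maps plus population transfer functions.

    ``mu = K @ nu + mu_ext`` and ``sigma^2 = K2 @ nu + sig2_ext`` with ``K``
    built from in-degrees and (signed) weights; ``dq2_ext`` is the quenched
    external contribution to the spatial variance of the mean input.
    """

    def __init__(self, K, K2, mu_ext, sig2_ext, dq2_ext, tau_m, tau_ref, V_r, V_th, tau_s, p, n_e_pops):
        self.K = np.asarray(K, dtype=float)
        self.K2 = np.asarray(K2, dtype=float)
        self.mu_ext = np.asarray(mu_ext, dtype=float)
        self.sig2_ext = np.asarray(sig2_ext, dtype=float)
        self.dq2_ext = np.asarray(dq2_ext, dtype=float)
        self.tau_m = np.asarray(tau_m, dtype=float)
        self.tau_ref = np.asarray(tau_ref, dtype=float)
        self.V_r = np.asarray(V_r, dtype=float)
        self.V_th = np.asarray(V_th, dtype=float)
        self.tau_s = float(tau_s)
        self.p = p
        self.n_e_pops = n_e_pops
        self.n_pops = self.K.shape[0]

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_clustered(cls, arch: ArchitectureParams, neuron: NeuronParams,
                       dH_E: float = 0.0, dH_I: float = 0.0) -> "MeanFieldModel":
        from .network import depressed_intercluster_weight

        p = arch.p
        n = 2 * (p + 1)
        K = np.zeros((n, n))
        K2 = np.zeros((n, n))
        mu_ext = np.zeros(n)
        sig2_ext = np.zeros(n)
        dq2_ext = np.zeros(n)
        pops = [("E", g) for g in range(p + 1)] + [("I", g) for g in range(p + 1)]

        def idx(b, lam):
            return lam if b == "E" else (p + 1 + lam)

        for i, (a, g) in enumerate(pops):
            for b in ("E", "I"):
                C = arch.C(a, b)
                f = arch.f(b)
                J = arch.J(a, b)
                Jp = arch.Jplus(a, b)
                Jm = depressed_intercluster_weight(J, Jp, arch.f(a), f, p)
                if g < p:  # clustered post population
                    for lam in range(p):
                        w = Jp if lam == g else Jm
                        K[i, idx(b, lam)] += C * f * w
                        K2[i, idx(b, lam)] += C * f * w ** 2
                    K[i, idx(b, p)] += (1 - p * f) * C * Jm
                    K2[i, idx(b, p)] += (1 - p * f) * C * Jm ** 2
                else:  # background post population
                    for lam in range(p):
                        K[i, idx(b, lam)] += C * f * Jm
                        K2[i, idx(b, lam)] += C * f * Jm ** 2
                    K[i, idx(b, p)] += (1 - p * f) * C * J
                    K2[i, idx(b, p)] += (1 - p * f) * C * J ** 2
            C_ext = getattr(arch, f"C_ext_{a}")
            J_ext = getattr(arch, f"J_ext_{a}")
            nu_o = getattr(arch, f"nu_o_{a}")
            mu_ext[i] = C_ext * J_ext * nu_o
            sig2_ext[i] = C_ext * J_ext ** 2 * nu_o
            dH = dH_E if a == "E" else dH_I
            dq2_ext[i] = (C_ext * J_ext * dH * nu_o) ** 2

        def pv(name):
            return np.array([getattr(neuron, f"{name}_{a}") for a, _ in pops])

        tau_s = 0.5 * (neuron.tau_syn_E + neuron.tau_syn_I)
        return cls(K, K2, mu_ext, sig2_ext, dq2_ext, pv("tau_m"), pv("tau_ref"),
                   pv("V_r"), pv("V_thresh"), tau_s, p, p + 1)

    @classmethod
    def from_reduced(cls, red: "ReducedArchitecture", neuron: NeuronParams,
                     dH_E: float = 0.0) -> "MeanFieldModel":
        # populations: [E1, E2, Eb, Ib]; inter-cluster E weights NOT depressed
        f = red.f
        K = np.zeros((4, 4))
        K2 = np.zeros((4, 4))
        C_EE = int(round(red.p_EE * red.N_E))
        C_EI = int(round(red.p_EI * red.N_I))
        C_IE = int(round(red.p_IE * red.N_E))
        C_II = int(round(red.p_II * red.N_I))
        for i, post in enumerate(["E1", "E2", "Eb", "Ib"]):
            CE, CI = (C_EE, C_EI) if post != "Ib" else (C_IE, C_II)
            JE, JI = (red.J_EE, red.J_EI) if post != "Ib" else (red.J_IE, red.J_II)
            for j, pre in enumerate(["E1", "E2", "Eb"]):
                if pre == "Eb":
                    w = (1 - 2 * f) * CE * JE
                    w2 = (1 - 2 * f) * CE * JE ** 2
                else:
                    Jw = red.Jplus_EE if (post == pre) else JE
                    w = f * CE * Jw
                    w2 = f * CE * Jw ** 2
                K[i, j] += w
                K2[i, j] += w2
            K[i, 3] += CI * JI
            K2[i, 3] += CI * JI ** 2
        mu_ext = np.zeros(4)
        sig2_ext = np.zeros(4)
        dq2_ext = np.zeros(4)
        for i, post in enumerate(["E1", "E2", "Eb", "Ib"]):
            a = "I" if post == "Ib" else "E"
            C_ext = getattr(red, f"C_ext_{a}")
            J_ext = getattr(red, f"J_ext_{a}")
            nu_o = getattr(red, f"nu_o_{a}")
            mu_ext[i] = C_ext * J_ext * nu_o
            sig2_ext[i] = C_ext * J_ext ** 2 * nu_o
            if a == "E":
                dq2_ext[i] = (C_ext * J_ext * dH_E * nu_o) ** 2
        alphas = ["E", "E", "E", "I"]
        tau_s = 0.5 * (neuron.tau_syn_E + neuron.tau_syn_I)
        return cls(K, K2, mu_ext, sig2_ext, dq2_ext,
                   np.array([getattr(neuron, f"tau_m_{a}") for a in alphas]),
                   np.array([getattr(neuron, f"tau_ref_{a}") for a in alphas]),
                   np.array([getattr(neuron, f"V_r_{a}") for a in alphas]),
                   np.array([getattr(neuron, f"V_thresh_{a}") for a in alphas]),
                   tau_s, 2, 3)

    # -- moment and rate maps -----------------------------------------------
    def moments(self, rates: np.ndarray) -> InputMoments:
        rates = np.asarray(rates, dtype=float)
        if rates.shape[-1] != self.n_pops:
            raise ValueError(f"expected rate vector of length {self.n_pops}")
        mu = self.K @ rates + self.mu_ext
        sig2 = self.K2 @ rates + self.sig2_ext
        return InputMoments(mu=mu, sigma=np.sqrt(sig2))

    def phi(self, mu, sigma):
        return _phi(mu, sigma, self.tau_m, self.tau_s, self.tau_ref, self.V_r, self.V_th)

    def rate_map(self, rates: np.ndarray) -> np.ndarray:
        m = self.moments(rates)
        return self.phi(m.mu, m.sigma)

    def quenched_maps(self, nu_bar: np.ndarray, s2: np.ndarray, z: np.ndarray, w: np.ndarray):
        """One application of the quenched self-consistency map.

        Returns (nu_bar', s2') given Gauss-Hermite nodes ``z`` with
        probabilists' weights ``w`` (summing to 1)."""
        mu_bar = self.K @ nu_bar + self.mu_ext
        sig2 = self.K2 @ nu_bar + self.sig2_ext
        delta2 = self.K2 @ s2 + self.dq2_ext
        delta = np.sqrt(np.maximum(delta2, 0.0))
        mu_z = mu_bar[None, :] + z[:, None] * delta[None, :]
        nu_z = self.phi(mu_z, np.sqrt(sig2)[None, :])
        nu_new = w @ nu_z
        s2_new = np.maximum(w @ nu_z ** 2 - nu_new ** 2, 0.0)
        return nu_new, s2_new


def mft_input_moments(rates, arch: ArchitectureParams, neuron: NeuronParams) -> InputMoments:
    """Input mean and noise per population for a given rate vector (ordered
    [E clusters, E background, I clusters, I background])."""
    return MeanFieldModel.from_clustered(arch, neuron).moments(np.asarray(rates, float))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _damped_fixed_point(fmap, x0, tol, max_iter, damping):
    """Damped fixed-point iteration with adaptive step size: the damping is
    grown while the residual shrinks and cut back when it grows."""
    x = np.asarray(x0, dtype=float).copy()
    eta = damping
    prev = np.inf
    res = np.inf
    for _ in range(max_iter):
        fx = fmap(x)
        delta = fx - x
        res = float(np.max(np.abs(delta)))
        if res < tol:
            return x, res, True
        if res > prev * 1.0001:
            eta = max(eta * 0.5, 0.02)
        else:
            eta = min(eta * 1.05, 1.0)
        prev = res
        x = x + eta * delta
    return x, res, False


def _classify(rates: np.ndarray, p: int, nA: int, rel_tol: float = 1e-4) -> str:
    e = rates[:p]
    scale = max(float(e.max()), 1e-9)
    if (e.max() - e.min()) < rel_tol * scale + 1e-9:
        return "uniform"
    thr = 0.5 * (e.max() + e.min())
    active = e > thr
    if nA == 0 or active.sum() != nA:
        return "not_found"
    if not active[:nA].all():
        return "not_found"
    up, down = e[:nA], e[nA:]
    ok = (up.max() - up.min()) < rel_tol * scale + 1e-9
    if nA < p:
        ok &= (down.max() - down.min()) < rel_tol * scale + 1e-9
        ok &= up.min() > down.max()
    return "cluster_state" if ok else "not_found"


def _seed_rates(model: MeanFieldModel, nA: int, nu_high: float, nu_low: float) -> np.ndarray:
    p = model.p
    nu = np.full(model.n_pops, nu_low, dtype=float)
    nu[:nA] = nu_high                      # first nA E clusters
    npop_e = model.n_e_pops
    nu[npop_e: npop_e + nA] = nu_high      # first nA I clusters
    return nu


def solve_mft(arch: ArchitectureParams, neuron: NeuronParams, nA: int,
              nu_high: float = 50.0, nu_low: float = 2.0, tol: float = 1e-10,
              max_iter: int = 20000, damping: float = 0.3,
              model: Optional[MeanFieldModel] = None) -> MFTSolution:
    """Solve the homogeneous self-consistency equations, biased toward a state
    with ``nA`` active clusters by the choice of initial rates."""
    if model is None:
        model = MeanFieldModel.from_clustered(arch, neuron)
    if not (0 <= nA <= model.p):
        raise ValueError("nA must lie in [0, p]")
    x0 = _seed_rates(model, nA, nu_high, nu_low)
    x, res, ok = _damped_fixed_point(model.rate_map, x0, tol, max_iter, damping)
    if not ok:
        sol = optimize.root(lambda v: model.rate_map(np.abs(v)) - np.abs(v), x, method="hybr")
        cand = np.abs(sol.x)
        res_c = float(np.max(np.abs(model.rate_map(cand) - cand)))
        if res_c < res:
            x, res = cand, res_c
        ok = res < tol
    kind = _classify(x, model.p, nA) if ok else "not_found"
    return MFTSolution(nA=nA, rates=x, residual=res, converged=ok, state_kind=kind, p=model.p)


def solve_quenched_mft(arch: ArchitectureParams, neuron: NeuronParams, dH: float,
                       nA: int, dH_I: float = 0.0, n_gh: int = 60,
                       nu_high: float = 50.0, nu_low: float = 2.0,
                       tol: float = 1e-10, max_iter: int = 20000,
                       damping: float = 0.3) -> MFTSolution:
    """Solve the quenched-disorder self-consistency for population rate means
    and spatial variances under the input-heterogeneity modulation ``dH``."""
    if dH < 0:
        raise ValueError("dH must be >= 0")
    model = MeanFieldModel.from_clustered(arch, neuron, dH_E=dH, dH_I=dH_I)
    z, w = hermegauss(n_gh)
    w = w / w.sum()
    n = model.n_pops
    nu0 = _seed_rates(model, nA, nu_high, nu_low)
    x0 = np.concatenate([nu0, np.zeros(n)])

    def fmap(x):
        nu_bar = np.maximum(x[:n], 0.0)
        s2 = np.maximum(x[n:], 0.0)
        nu_new, s2_new = model.quenched_maps(nu_bar, s2, z, w)
        return np.concatenate([nu_new, s2_new])

    x, res, ok = _damped_fixed_point(fmap, x0, tol, max_iter, damping)
    if not ok:
        sol = optimize.root(lambda v: fmap(v) - v, x, method="hybr")
        cand = sol.x
        res_c = float(np.max(np.abs(fmap(cand) - cand)))
        if res_c < res and np.all(cand[:n] > -1e-9):
            x, res = np.maximum(cand, 0.0), res_c
        ok = res < tol
    nu_bar, s2 = x[:n], x[n:]
    kind = _classify(nu_bar, model.p, nA) if ok else "not_found"
    return MFTSolution(nA=nA, rates=nu_bar, residual=res, converged=ok,
                       state_kind=kind, p=model.p, s2=s2)


def match_intracluster_coupling(nu_sim: float, arch: ArchitectureParams,
                                neuron: NeuronParams, coupling_grid=None,
                                nA: int = 3) -> Optional[dict]:
    """Find the intracluster E-to-E potentiation factor whose mean-field
    active-cluster rate (for the ``nA`` cluster state) best matches the
    simulated rate ``nu_sim``; returns None if no cluster state exists on
    the grid."""
    if coupling_grid is None:
        coupling_grid = np.arange(12.0, 19.5 + 1e-9, 0.025)
    best = None
    for fac in np.asarray(coupling_grid, dtype=float):
        a = replace(arch, Jplus_EE=fac * arch.J_EE)
        sol = solve_mft(a, neuron, nA)
        if sol.state_kind != "cluster_state":
            continue
        err = abs(sol.nu_up - nu_sim)
        if best is None or err < best["error"]:
            best = dict(coupling=float(fac), error=err, nu_mft=sol.nu_up)
    return best


# ---------------------------------------------------------------------------
# reduced 2-cluster effective theory
# ---------------------------------------------------------------------------


@dataclass
class ReducedArchitecture:
    """Two E clusters (no inter-cluster depression), one background E and one
    background I population."""

    N_E: int = 800
    N_I: int = 200
    f: float = 0.1
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    J_EE: float = 0.0
    J_EI: float = 0.0
    J_IE: float = 0.0
    J_II: float = 0.0
    Jplus_EE: float = 0.0
    C_ext_E: int = 0
    C_ext_I: int = 0
    J_ext_E: float = 0.0
    J_ext_I: float = 0.0
    nu_o_E: float = 7.0
    nu_o_I: float = 7.0

    def __post_init__(self):
        if not (0 < self.f <= 0.5):
            raise ValueError("f must lie in (0, 0.5]")


def default_reduced_architecture(jplus_factor: float = 9.0,
                                 config: str = "reduced") -> "ReducedArchitecture":
    """The shipped 2-cluster reduced network: two 80-cell E clusters (f=0.1 of
    N_E=800), unclustered background E and I populations, baseline weights
    from the reduced config, intracluster E-to-E coupling ``jplus_factor``
    times baseline and no inter-cluster depression. At this coupling the
    unmodulated network is bistable (two cluster attractors separated by the
    unstable uniform state)."""
    from .params import default_config
    cfg = default_config(config)
    a = cfg["architecture"]
    return ReducedArchitecture(
        N_E=800, N_I=200, f=0.1,
        p_EE=a.p_EE, p_EI=a.p_EI, p_IE=a.p_IE, p_II=a.p_II,
        J_EE=a.J_EE, J_EI=a.J_EI, J_IE=a.J_IE, J_II=a.J_II,
        Jplus_EE=jplus_factor * a.J_EE,
        C_ext_E=a.C_ext_E, C_ext_I=a.C_ext_I,
        J_ext_E=a.J_ext_E, J_ext_I=a.J_ext_I,
        nu_o_E=a.nu_o_E, nu_o_I=a.nu_o_I)


@dataclass
class FlowMap:
    """2D flow of the two in-focus cluster rates with adapted ambient rates."""

    grid: np.ndarray
    nu_out: np.ndarray           # (G, G, 2)
    nu_ambient: np.ndarray       # (G, G, 2)
    converged: np.ndarray        # (G, G) bool
    fixed_points: list           # dicts: point, stable, kind
    flow_fn: Callable = field(repr=False, default=None)

    @property
    def stable_points(self):
        return [fp for fp in self.fixed_points if fp["stable"]]

    @property
    def saddle_points(self):
        return [fp for fp in self.fixed_points if not fp["stable"]]


def _reduced_machinery(red: ReducedArchitecture, neuron: NeuronParams, dH: float, n_gh: int):
    model = MeanFieldModel.from_reduced(red, neuron, dH_E=dH)
    z, w = hermegauss(n_gh)
    w = w / w.sum()
    delta = np.sqrt(model.dq2_ext)  # firing-rate variance neglected (s2 = 0)

    def pop_rates(nu4):
        """z-averaged rates of all four populations at rate vector nu4."""
        mu = model.K @ nu4 + model.mu_ext
        sig = np.sqrt(model.K2 @ nu4 + model.sig2_ext)
        mu_z = mu[None, :] + z[:, None] * delta[None, :]
        return w @ model.phi(mu_z, sig[None, :])

    def ambient(nu1, nu2, guess):
        def fmap(amb):
            return pop_rates(np.array([nu1, nu2, amb[0], amb[1]]))[2:]
        amb, res, ok = _damped_fixed_point(fmap, np.asarray(guess, float),
                                           1e-10, 2000, 0.5)
        return amb, ok

    def flow(nu1, nu2, guess=(5.0, 8.0)):
        amb, ok = ambient(nu1, nu2, guess)
        full = np.array([nu1, nu2, amb[0], amb[1]])
        out = pop_rates(full)[:2]
        return out, amb, ok

    return model, pop_rates, ambient, flow


def effective_flow_map(red: ReducedArchitecture, neuron: NeuronParams,
                       dH: float = 0.0, grid=None, n_gh: int = 40,
                       nu_high: float = 60.0, nu_low: float = 1.0) -> FlowMap:
    """Compute the 2D effective flow map of the two in-focus cluster rates,
    with ambient background populations adapted self-consistently at each
    frozen pair of in-focus rates, plus its fixed points."""
    model, pop_rates, ambient, flow = _reduced_machinery(red, neuron, dH, n_gh)

    if grid is None:
        grid = np.zeros(0)
        nu_out = np.zeros((0, 0, 2))
        nu_amb = np.zeros((0, 0, 2))
        conv = np.zeros((0, 0), dtype=bool)
    else:
        grid = np.asarray(grid, dtype=float)
        G = len(grid)
        nu_out = np.zeros((G, G, 2))
        nu_amb = np.zeros((G, G, 2))
        conv = np.zeros((G, G), dtype=bool)
        guess = np.array([5.0, 8.0])
        for i, nu1 in enumerate(grid):
            row_guess = guess.copy()
            for j, nu2 in enumerate(grid):
                out, amb, ok = flow(nu1, nu2, row_guess)
                nu_out[i, j] = out
                nu_amb[i, j] = amb
                conv[i, j] = ok
                row_guess = amb
                if j == 0:
                    guess = amb.copy()

    # fixed points: self-consistent solutions of the full 4-population system
    seeds = [
        np.array([nu_high, nu_low, 5.0, 8.0]),
        np.array([nu_low, nu_high, 5.0, 8.0]),
        np.array([0.5 * (nu_high + nu_low)] * 2 + [5.0, 8.0]),
        np.array([nu_low, nu_low, 5.0, 8.0]),
    ]
    fps = []
    for s0 in seeds:
        x, res, ok = _damped_fixed_point(pop_rates, s0, 1e-11, 1500, 0.3)
        if not ok:
            sol = optimize.root(lambda v: pop_rates(np.abs(v)) - np.abs(v), x,
                                method="hybr")
            cand = np.abs(sol.x)
            res_c = float(np.max(np.abs(pop_rates(cand) - cand)))
            if res_c < res:
                x, res = cand, res_c
            ok = res < 1e-9
        if not ok:
            continue
        if any(np.max(np.abs(x[:2] - fp["point"])) < 1e-5 for fp in fps):
            continue
        # stability of the 2D map nu_in -> nu_out (ambient adapted)
        eps = 1e-4
        Jm = np.zeros((2, 2))
        base, amb0, _ = flow(x[0], x[1], x[2:])
        for k in range(2):
            pert = x[:2].copy()
            pert[k] += eps
            outp, _, _ = flow(pert[0], pert[1], x[2:])
            Jm[:, k] = (outp - base) / eps
        eig = np.linalg.eigvals(Jm - np.eye(2))
        stable = bool(np.all(eig.real < 0))
        kind = "uniform" if abs(x[0] - x[1]) < 1e-4 * max(x[0], 1.0) else "cluster_state"
        fps.append(dict(point=x[:2].copy(), ambient=x[2:].copy(), stable=stable, kind=kind))

    return FlowMap(grid=grid, nu_out=nu_out, nu_ambient=nu_amb, converged=conv,
                   fixed_points=fps, flow_fn=flow)


@dataclass
class EffectivePotential:
    """1D potential along the path joining the two cluster attractors."""

    path_coord: np.ndarray
    potential: np.ndarray
    wells: np.ndarray
    saddle: Optional[np.ndarray]
    barrier_height: float


def effective_potential(flow_map: FlowMap, n_points: int = 80) -> EffectivePotential:
    """Integrate the 2D flow along the piecewise-linear path
    well -> saddle -> well to obtain a 1D potential and its barrier height.

    With fewer than two stable fixed points (or no saddle) the landscape is a
    single well and the barrier height is 0.
    """
    stable = flow_map.stable_points
    saddles = [fp for fp in flow_map.saddle_points if fp["kind"] == "uniform"]
    if len(stable) < 2 or not saddles:
        pt = stable[0]["point"] if stable else np.zeros(2)
        return EffectivePotential(path_coord=np.array([0.0]), potential=np.array([0.0]),
                                  wells=np.atleast_2d(pt), saddle=None, barrier_height=0.0)
    cluster_wells = [fp for fp in stable if fp["kind"] == "cluster_state"]
    if len(cluster_wells) < 2:
        cluster_wells = stable
    w1 = cluster_wells[0]["point"]
    w2 = cluster_wells[1]["point"]
    sd = saddles[0]["point"]

    def segment(a, b):
        ts = np.linspace(0.0, 1.0, n_points)
        return a[None, :] + ts[:, None] * (b - a)[None, :]

    path = np.vstack([segment(w1, sd), segment(sd, w2)[1:]])
    amb_guess = saddles[0]["ambient"]
    F = np.zeros_like(path)
    guess = cluster_wells[0]["ambient"]
    for k, (x, y) in enumerate(path):
        out, amb, _ = flow_map.flow_fn(x, y, guess)
        F[k] = out - np.array([x, y])
        guess = amb
    dl = np.diff(path, axis=0)
    Fmid = 0.5 * (F[1:] + F[:-1])
    dU = -np.sum(Fmid * dl, axis=1)
    U = np.concatenate([[0.0], np.cumsum(dU)])
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(dl, axis=1))])
    i_sd = n_points - 1
    h = float(U[i_sd] - 0.5 * (U[0] + U[-1]))
    return EffectivePotential(path_coord=s, potential=U,
                              wells=np.vstack([w1, w2]), saddle=sd,
                              barrier_height=max(h, 0.0))
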