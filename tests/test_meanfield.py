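import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import quad
from scipy.special import erfcx

from arousalnet import meanfield as mf
from arousalnet.network import build_clustered
from arousalnet.params import NeuronParams


class TestTransferFunction:
    def test_integral_matches_quad(self):
        rng = np.random.default_rng(0)

        def ref(a, b):
            g = lambda x: erfcx(-x) if x <= 0 else 2 * np.exp(x ** 2) - erfcx(x)
            return quad(g, a, b, limit=200)[0]

        for _ in range(20):
            a = rng.uniform(-8, 3)
            b = a + rng.uniform(0.1, 8)
            if b > 12:
                continue
            assert mf._integral_exp_erfc(a, b) == pytest.approx(ref(a, b), rel=1e-10)

    def test_rate_vanishes_for_strongly_negative_drive(self, neuron):
        assert mf.transfer_rate(-500.0, 5.0, neuron) == pytest.approx(0.0, abs=1e-12)

    def test_rate_bounded_by_refractory_period(self, neuron):
        rates = mf.transfer_rate(np.array([50, 200, 1000.0]), 10.0, neuron)
        assert (rates < 1.0 / neuron.tau_ref_E).all()

    def test_monotone_in_mean_input(self, neuron):
        mus = np.linspace(-20, 120, 40)
        r = mf.transfer_rate(mus, 6.0, neuron)
        assert (np.diff(r) >= -1e-12).all()

    def test_sigma_must_be_positive(self, neuron):
        with pytest.raises(ValueError):
            mf.transfer_rate(10.0, 0.0, neuron)

    def test_matches_single_neuron_simulation(self, neuron):
        """Simulation oracle in the fluctuation-driven regime (one point; the
        full grid runs in the acceptance suite)."""
        from arousalnet.simulate import simulate_single_neuron
        mu, sig = 76.0, 1.4
        pred = mf.transfer_rate(mu, sig, neuron)
        sim = simulate_single_neuron(mu, sig, neuron, duration=60.0, seed=4)
        assert pred == pytest.approx(sim, rel=0.12)


class TestInputMoments:
    def test_zero_rates_leave_external_only(self, small_arch, neuron):
        m = mf.mft_input_moments(np.zeros(2 * (small_arch.p + 1)), small_arch, neuron)
        mu_ext_E = small_arch.C_ext_E * small_arch.J_ext_E * small_arch.nu_o_E
        assert np.allclose(m.mu[: small_arch.p + 1], mu_ext_E)

    def test_symmetric_rates_give_symmetric_moments(self, small_arch, neuron):
        arch = replace(small_arch, Jplus_EE=small_arch.J_EE,
                       Jplus_EI=small_arch.J_EI, Jplus_IE=small_arch.J_IE,
                       Jplus_II=small_arch.J_II)
        p = arch.p
        nu = np.concatenate([np.full(p + 1, 5.0), np.full(p + 1, 9.0)])
        m = mf.mft_input_moments(nu, arch, neuron)
        assert np.allclose(m.mu[:p], m.mu[0])
        assert np.allclose(m.mu[p + 1: 2 * p + 1], m.mu[p + 1])

    def test_matches_realized_network_ensemble(self, small_arch, neuron):
        """mu coefficients equal the ensemble-average input of realized
        instances (oracle: direct summation over built weight matrices)."""
        p = small_arch.p
        rng = np.random.default_rng(3)
        nu = rng.uniform(1, 20, size=2 * (p + 1))
        model = mf.MeanFieldModel.from_clustered(small_arch, neuron)
        mu_pred = model.moments(nu).mu
        # per-cell rate vector for a realized instance
        acc = None
        n_inst = 8
        for k in range(n_inst):
            inst = build_clustered(small_arch, neuron, seed=100 + k)
            rate_of = np.empty(inst.N)
            pop_idx = np.where(inst.pop_of == 0, 0, p + 1) + inst.cluster_of
            rate_of = nu[pop_idx]
            w_in = inst.W @ rate_of
            ext = np.where(inst.pop_of == 0,
                           small_arch.C_ext_E * small_arch.J_ext_E * small_arch.nu_o_E,
                           small_arch.C_ext_I * small_arch.J_ext_I * small_arch.nu_o_I)
            total = w_in + ext
            # average within populations
            pop_mu = np.array([total[pop_idx == q].mean() for q in range(2 * (p + 1))])
            acc = pop_mu if acc is None else acc + pop_mu
        assert np.allclose(acc / n_inst, mu_pred, rtol=0.03)


class TestSolvers:
    def test_uniform_seed_finds_symmetric_state(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        sol = mf.solve_mft(a, n, nA=0)
        assert sol.converged and sol.state_kind == "uniform"
        assert sol.residual < 1e-8
        e = sol.e_cluster_rates
        assert e.max() - e.min() < 1e-6

    def test_cluster_state_and_residual(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        sol = mf.solve_mft(a, n, nA=1)
        assert sol.state_kind == "cluster_state"
        assert sol.residual < 1e-8
        assert sol.nu_up > sol.nu_down

    def test_cluster_state_requires_strong_coupling(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        weak = replace(a, Jplus_EE=1.5 * a.J_EE)
        sol = mf.solve_mft(weak, n, nA=1)
        assert sol.state_kind in ("uniform", "not_found")

    def test_rates_within_physical_bounds(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        for nA in (0, 1, 2):
            sol = mf.solve_mft(a, n, nA=nA)
            assert (sol.rates >= 0).all()
            assert (sol.rates <= 1 / n.tau_ref_E).all()

    def test_quenched_reduces_to_plain_at_zero_disorder(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        plain = mf.solve_mft(a, n, nA=1)
        quenched = mf.solve_quenched_mft(a, n, dH=0.0, nA=1)
        assert quenched.converged
        assert np.allclose(quenched.rates, plain.rates, atol=1e-6)
        assert np.allclose(quenched.s2, 0.0, atol=1e-6)

    def test_quadrature_refinement_agrees(self, reduced_cfg):
        """One application of the quenched map at 40 vs 80 nodes."""
        from numpy.polynomial.hermite_e import hermegauss
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        model = mf.MeanFieldModel.from_clustered(a, n, dH_E=0.2)
        rng = np.random.default_rng(1)
        nu = rng.uniform(1, 30, model.n_pops)
        s2 = rng.uniform(0, 20, model.n_pops)
        outs = []
        for n_gh in (40, 80):
            z, w = hermegauss(n_gh)
            w = w / w.sum()
            outs.append(np.concatenate(model.quenched_maps(nu, s2, z, w)))
        assert np.allclose(outs[0], outs[1], atol=1e-8)

    def test_invalid_nA_rejected(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        with pytest.raises(ValueError):
            mf.solve_mft(a, n, nA=a.p + 1)

    def test_match_coupling_returns_exact_grid_point(self, reduced_cfg):
        a, n = reduced_cfg["architecture"], reduced_cfg["neuron"]
        grid = [8.5, 9.0, 9.5]
        target = mf.solve_mft(replace(a, Jplus_EE=9.0 * a.J_EE), n, nA=1).nu_up
        best = mf.match_intracluster_coupling(target, a, n,
                                              coupling_grid=grid, nA=1)
        assert best["coupling"] == pytest.approx(9.0)
        assert best["error"] < 1e-9


@pytest.fixture(scope="module")
def flow0(reduced_cfg):
    red = mf.default_reduced_architecture()
    return mf.effective_flow_map(red, reduced_cfg["neuron"], dH=0.0,
                                 grid=np.linspace(0, 60, 9), n_gh=20)


class TestEffectiveTheory:
    def test_bistable_fixed_point_structure(self, flow0):
        stable = flow0.stable_points
        saddles = [fp for fp in flow0.saddle_points if fp["kind"] == "uniform"]
        assert len(stable) == 2
        assert len(saddles) >= 1
        for fp in stable:
            assert fp["kind"] == "cluster_state"

    def test_flow_map_exchange_symmetry(self, flow0):
        out = flow0.nu_out
        assert np.allclose(out[..., 0], out.transpose(1, 0, 2)[..., 1], atol=1e-6)

    def test_fixed_points_match_reduced_mft(self, flow0, reduced_cfg):
        """Fixed points of the map are self-consistent states: the flow
        vanishes there."""
        for fp in flow0.fixed_points:
            x, y = fp["point"]
            out, _, ok = flow0.flow_fn(x, y, fp["ambient"])
            assert ok
            assert np.allclose(out, [x, y], atol=1e-6)

    def test_potential_two_equal_wells(self, flow0):
        pot = mf.effective_potential(flow0)
        assert pot.barrier_height > 0
        assert pot.potential[0] == pytest.approx(0.0)
        assert pot.potential[-1] == pytest.approx(0.0, abs=1e-4 * max(1, pot.barrier_height))

    def test_single_well_has_zero_barrier(self, reduced_cfg):
        red = mf.default_reduced_architecture(jplus_factor=3.0)
        fmap = mf.effective_flow_map(red, reduced_cfg["neuron"], dH=0.0, n_gh=20)
        pot = mf.effective_potential(fmap)
        assert len(fmap.stable_points) == 1
        assert pot.barrier_height == 0.0
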