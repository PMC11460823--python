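import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arousalnet.network import (assign_external_rates, build_clustered,
                                build_uniform, depressed_intercluster_weight,
                                make_stimulus_set,
                                random_conserving_architecture,
                                stimulus_current, stimulus_timecourse)
from arousalnet.params import ArousalModulation, StimulusSpec


class TestDepressedWeight:
    def test_no_potentiation_collapses_to_baseline(self):
        assert depressed_intercluster_weight(0.3, 0.3, 0.1, 0.07, 5) == pytest.approx(0.3)

    def test_degenerate_fractions_raise(self):
        with pytest.raises(ValueError):
            depressed_intercluster_weight(0.3, 0.6, 0.0, 0.0, 5)

    @given(J=st.floats(0.01, 1.0), ratio=st.floats(1.0, 3.0),
           f=st.floats(0.02, 0.12), p=st.integers(2, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weight_balance_identity(self, J, ratio, f, p):
        """J- satisfies the per-cell weight-sum identity behind conservation."""
        Jp = ratio * J
        Jm = depressed_intercluster_weight(J, Jp, f, f, p)
        lhs = (p * f * (f * Jp + (1 - f) * Jm)
               + (1 - p * f) * (p * f * Jm + (1 - p * f) * J))
        assert lhs == pytest.approx(J, rel=1e-12)


class TestBuild:
    def test_uniform_in_degrees_exact(self, small_uniform, small_arch):
        W = small_uniform.W.tocsr()
        for a, ids in (("E", small_uniform.e_cells), ("I", small_uniform.i_cells)):
            for b, pool in (("E", small_uniform.e_cells), ("I", small_uniform.i_cells)):
                C = small_arch.C(a, b)
                for i in ids[:25]:
                    row = W.getrow(i)
                    n_b = np.isin(row.indices, pool).sum()
                    assert n_b == C

    def test_clustered_in_degrees_exact(self, small_clustered, small_arch):
        W = small_clustered.W.tocsr()
        counts = np.diff(W.indptr)
        C_tot_E = small_arch.C("E", "E") + small_arch.C("E", "I")
        C_tot_I = small_arch.C("I", "E") + small_arch.C("I", "I")
        assert (counts[small_clustered.pop_of == 0] == C_tot_E).all()
        assert (counts[small_clustered.pop_of == 1] == C_tot_I).all()

    def test_no_self_connections(self, small_clustered):
        assert small_clustered.W.diagonal().sum() == 0

    def test_same_seed_identical(self, small_arch, neuron):
        a = build_clustered(small_arch, neuron, seed=3)
        b = build_clustered(small_arch, neuron, seed=3)
        assert (a.W != b.W).nnz == 0
        assert np.array_equal(a.cluster_of, b.cluster_of)

    def test_total_synapse_count_matches_uniform(self, small_clustered, small_uniform):
        assert small_clustered.W.nnz == small_uniform.W.nnz

    def test_weight_sum_conserved_exactly(self, small_clustered, small_uniform):
        su = small_uniform.W.data.sum()
        sc = small_clustered.W.data.sum()
        assert sc == pytest.approx(su, rel=1e-10)

    def test_weight_sum_random_architectures(self, neuron):
        rng = np.random.default_rng(5)
        for _ in range(5):
            arch = random_conserving_architecture(rng)
            u = build_uniform(arch, neuron, seed=1)
            c = build_clustered(arch, neuron, seed=1)
            assert c.W.data.sum() == pytest.approx(u.W.data.sum(), rel=1e-10)

    def test_within_cluster_ee_weights_potentiated(self, small_clustered, small_arch):
        W = small_clustered.W.tocsr()
        mem = small_clustered.cluster_members(0, "E")
        sub = W[np.ix_(mem, mem)].toarray()
        vals = sub[sub != 0]
        assert np.allclose(vals, small_arch.Jplus_EE)

    def test_infeasible_in_degree_raises(self, small_arch, neuron):
        from dataclasses import replace
        bad = replace(small_arch, p_EI=1.5)
        with pytest.raises(ValueError):
            build_uniform(bad, neuron, seed=0)


class TestExternalRates:
    def test_no_modulation_is_baseline(self, small_clustered, small_arch):
        mod = ArousalModulation(kind="heterogeneity", dH_E=0.0, seed=1)
        nu = assign_external_rates(small_clustered, mod)
        assert np.allclose(nu[small_clustered.pop_of == 0], small_arch.nu_o_E)

    def test_mean_modulation_shifts_uniformly(self, small_clustered, small_arch):
        mod = ArousalModulation(kind="mean", dM_E=0.3)
        nu = assign_external_rates(small_clustered, mod)
        e = small_clustered.pop_of == 0
        assert np.allclose(nu[e], small_arch.nu_o_E * 1.3)
        assert np.allclose(nu[~e], small_arch.nu_o_I)

    def test_heterogeneity_variance_matches(self, neuron):
        """Pre-clipping spread of external rates is (dH * nu_o)^2."""
        from arousalnet.params import ArchitectureParams
        arch = ArchitectureParams(
            N_E=2000, N_I=500, p=2, f_E=0.05, f_I=0.05,
            p_EE=0.1, p_EI=0.2, p_IE=0.2, p_II=0.2,
            J_EE=0.05, J_EI=-0.2, J_IE=0.05, J_II=-0.15, Jplus_EE=0.1,
            Jplus_EI=-0.2, Jplus_IE=0.05, Jplus_II=-0.15,
            C_ext_E=10, C_ext_I=10, J_ext_E=0.1, J_ext_I=0.1)
        inst = build_uniform(arch, neuron, seed=2)
        dH = 0.2
        mod = ArousalModulation(kind="heterogeneity", dH_E=dH, dH_I=dH, seed=4)
        nu = assign_external_rates(inst, mod)
        target_var = (dH * arch.nu_o_E) ** 2
        assert nu.var() == pytest.approx(target_var, rel=0.15)

    def test_large_dh_clips_at_zero(self, small_clustered):
        mod = ArousalModulation(kind="heterogeneity", dH_E=2.0, dH_I=2.0, seed=9)
        nu = assign_external_rates(small_clustered, mod)
        assert nu.min() == 0.0

    def test_clusters_share_disorder_realization(self, small_clustered, small_arch):
        mod = ArousalModulation(kind="heterogeneity", dH_E=0.3, seed=21)
        nu = assign_external_rates(small_clustered, mod)
        p = small_arch.p
        slots = small_clustered.slot_of
        per_cluster = []
        for c in range(p):
            mem = small_clustered.cluster_members(c, "E")
            per_cluster.append(nu[mem[np.argsort(slots[mem])]])
        for arr in per_cluster[1:]:
            assert np.allclose(arr, per_cluster[0])


class TestStimulus:
    def test_zero_before_onset_and_at_onset(self):
        s = stimulus_timecourse(np.array([0.0, 0.5, 1.0]), 0.05, 0.15, t_stim=1.0)
        assert np.allclose(s, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_peak_normalized_to_one(self, seed):
        rng = np.random.default_rng(seed)
        tau_r = rng.uniform(0.005, 0.1)
        tau_d = tau_r + rng.uniform(0.01, 0.3)
        t = np.linspace(0, 3.0, 400000)
        s = stimulus_timecourse(t, tau_r, tau_d, t_stim=0.0)
        assert s.max() == pytest.approx(1.0, abs=1e-6)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            stimulus_timecourse(0.1, 0.2, 0.1)

    def test_stimulus_set_counts(self, small_clustered, small_arch):
        specs = make_stimulus_set(small_clustered, n_stimuli=5, seed=0)
        assert len(specs) == 5
        n_clus = round(0.5 * small_arch.p)
        m = round(small_arch.f_E * small_arch.N_E)
        for sp in specs:
            assert len(sp.targeted_clusters) == n_clus
            assert len(sp.targeted_cells) == n_clus * round(0.5 * m)
            assert (small_clustered.pop_of[sp.targeted_cells] == 0).all()

    def test_saturated_fractions_target_all_clustered_cells(self, small_clustered, small_arch):
        sp = make_stimulus_set(small_clustered, 1, frac_clusters=1.0,
                               frac_cells=1.0, seed=0)[0]
        expected = sum(len(small_clustered.cluster_members(c, "E"))
                       for c in range(small_arch.p))
        assert len(sp.targeted_cells) == expected

    def test_uniform_matched_count(self, small_uniform, small_clustered):
        su = make_stimulus_set(small_uniform, 3, seed=1)
        sc = make_stimulus_set(small_clustered, 3, seed=1)
        assert len(su[0].targeted_cells) == len(sc[0].targeted_cells)

    def test_bad_fraction_rejected(self, small_clustered):
        with pytest.raises(ValueError):
            make_stimulus_set(small_clustered, 1, frac_clusters=1.5)

    def test_current_scaling(self):
        spec = StimulusSpec(stim_id=0, targeted_clusters=[0], targeted_cells=[0],
                            A_stim_E=0.1, tau_r=0.01, tau_d=0.1, t_stim=0.0)
        t = np.linspace(0, 1, 20000)
        cur = stimulus_current(t, spec, nu_o=7.0, C_ext=100, J_ext=0.05)
        assert cur.max() == pytest.approx(0.1 * 7.0 * 100 * 0.05, rel=1e-4)
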