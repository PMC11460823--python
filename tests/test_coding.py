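import numpy as np
import pandas as pd
import pytest

from arousalnet import coding


def synthetic_counts(kind, n_classes=5, n_per=12, n_units=20, n_windows=6, seed=0):
    """Poisson count matrices: 'separable' gives disjoint unit groups with
    high rates per class in evoked windows; 'noise' is label-independent."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), n_per)
    counts = rng.poisson(1.0, size=(n_classes * n_per, n_units, n_windows))
    if kind == "separable":
        per = n_units // n_classes
        for k, lab in enumerate(labels):
            counts[k, lab * per:(lab + 1) * per, n_windows // 2:] += 20
    return coding.CountMatrix(counts=counts, labels=labels,
                              window_centers=np.linspace(-0.05, 0.45, n_windows),
                              window=0.1, step=0.1, unit_ids=np.arange(n_units))


class TestSlidingCounts:
    def test_total_counts_match_spikes_in_span(self, small_trialset):
        cm = coding.sliding_counts(small_trialset, window=0.1, step=0.1,
                                   span=(-0.1, 0.6))
        df = small_trialset.spikes
        rel = df["time_s"] - small_trialset.t_stim
        in_span = ((rel >= -0.1) & (rel < 0.6)).sum()
        assert cm.counts.sum() == in_span

    def test_single_spike_hits_every_overlapping_window(self, small_trialset):
        cm = coding.sliding_counts(small_trialset, window=0.1, step=0.02,
                                   span=(-0.1, 0.6))
        # windows overlap 5x at step 0.02: a spike at t=0 lands in the windows
        # whose start lies in (-0.1, 0]
        starts = cm.window_centers - 0.05
        n_cover = ((starts <= 1e-9) & (starts + 0.1 > 1e-9)).sum()
        assert n_cover == 5

    def test_span_shorter_than_window_rejected(self, small_trialset):
        with pytest.raises(ValueError):
            coding.sliding_counts(small_trialset, window=0.2, span=(0, 0.1))


class TestDecoding:
    def test_separable_counts_decoded_perfectly(self):
        cm = synthetic_counts("separable")
        res = coding.decode_timecourse(cm, n_repeats=2, seed=0)
        assert res.peak_accuracy == 1.0
        assert res.accuracy[-1] == 1.0
        assert res.accuracy[0] < 0.6

    def test_permuted_labels_at_chance(self):
        cm = synthetic_counts("separable", n_per=16)
        rng = np.random.default_rng(1)
        cm.labels = rng.permutation(cm.labels)
        res = coding.decode_timecourse(cm, n_repeats=4, seed=0)
        assert abs(res.accuracy.mean() - 0.2) < 0.08

    def test_unit_reordering_invariance(self):
        cm = synthetic_counts("separable")
        perm = np.random.default_rng(2).permutation(cm.counts.shape[1])
        cm2 = coding.CountMatrix(counts=cm.counts[:, perm, :], labels=cm.labels,
                                 window_centers=cm.window_centers, window=0.1,
                                 step=0.1, unit_ids=cm.unit_ids)
        r1 = coding.decode_timecourse(cm, n_repeats=2, seed=3)
        r2 = coding.decode_timecourse(cm2, n_repeats=2, seed=3)
        assert np.allclose(r1.accuracy, r2.accuracy)

    def test_too_few_trials_per_class_raises(self):
        cm = synthetic_counts("noise", n_per=3)
        with pytest.raises(ValueError):
            coding.decode_timecourse(cm, n_folds=5)

    def test_balance_labels_subsamples_equally(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 10 + [1] * 7 + [2] * 13)
        keep = coding.balance_labels(labels, rng)
        _, counts = np.unique(labels[keep], return_counts=True)
        assert (counts == 7).all()


class TestShuffleNull:
    def test_null_centered_at_chance(self):
        cm = synthetic_counts("separable", n_per=12)
        null, pct = coding.shuffle_null(cm, n_shuffles=60, seed=0)
        assert abs(null.mean() - 0.2) < 0.05

    def test_informative_peak_beats_null(self):
        cm = synthetic_counts("separable")
        res = coding.decode_timecourse(cm, n_repeats=2, seed=0)
        null, pct = coding.shuffle_null(cm, n_shuffles=40, seed=1)
        assert res.peak_accuracy > pct[res.peak_window]

    def test_zero_shuffles(self):
        cm = synthetic_counts("noise")
        null, pct = coding.shuffle_null(cm, n_shuffles=0)
        assert null.shape[0] == 0 and pct is None


class TestFeatureSampling:
    def test_feature_count_is_p_plus_one(self, small_trialset):
        p = int(small_trialset.unit_cluster[small_trialset.unit_pop == 0].max())
        res = coding.model_feature_sample(small_trialset, n_runs=1, seed=0,
                                          n_repeats=1, n_folds=4)
        assert 0 <= res.peak_accuracy <= 1
        assert res.window_centers.shape == res.accuracy.shape
        assert p == 9

    def test_accuracy_between_chance_and_one(self, small_trialset):
        res = coding.model_feature_sample(small_trialset, n_runs=3, seed=1,
                                          n_repeats=1, n_folds=4)
        assert 0.1 < res.peak_accuracy <= 1.0


class TestDprime:
    def test_equal_means_give_zero(self):
        counts = np.ones((20, 3, 2))
        labels = np.array([0, 1] * 10)
        # identical within-class patterns: equal means, nonzero variance
        counts[labels == 0] += np.tile([0, 1], 5)[:, None, None]
        counts[labels == 1] += np.tile([0, 1], 5)[:, None, None]
        cm = coding.CountMatrix(counts=counts, labels=labels,
                                window_centers=np.array([0.0, 0.1]),
                                window=0.1, step=0.1, unit_ids=np.arange(3))
        res = coding.dprime_pipeline(cm)
        assert np.allclose(res.dprime_cell_time, 0.0)

    def test_textbook_value(self):
        """mu_a=2, mu_b=0, sigma_a=sigma_b=1 gives d' = 2."""
        rng = np.random.default_rng(0)
        n = 4000
        a = rng.normal(2, 1, n)
        b = rng.normal(0, 1, n)
        counts = np.concatenate([a, b])[:, None, None]
        labels = np.array([0] * n + [1] * n)
        cm = coding.CountMatrix(counts=counts, labels=labels,
                                window_centers=np.array([0.0]), window=0.1,
                                step=0.1, unit_ids=np.array([0]))
        res = coding.dprime_pipeline(cm)
        assert res.Dsc_prime == pytest.approx(2.0, rel=0.05)

    def test_zero_variance_pairs_dropped(self):
        counts = np.zeros((12, 1, 1))
        labels = np.repeat([0, 1, 2], 4)
        counts[labels == 2] = np.arange(4)[:, None, None]  # only class 2 varies
        cm = coding.CountMatrix(counts=counts, labels=labels,
                                window_centers=np.array([0.0]), window=0.1,
                                step=0.1, unit_ids=np.array([0]))
        res = coding.dprime_pipeline(cm)
        assert np.isfinite(res.Dsc_prime)

    def test_shuffled_labels_reduce_dprime(self):
        cm = synthetic_counts("separable", n_per=20)
        informative = coding.dprime_pipeline(cm).Dsc_prime
        rng = np.random.default_rng(3)
        cm.labels = rng.permutation(cm.labels)
        assert coding.dprime_pipeline(cm).Dsc_prime < 0.5 * informative


class TestConditionNormalize:
    def test_zero_variance_session_excluded(self):
        out = coding.condition_normalize_and_bin({"s1": [(10, 1.0), (50, 1.0)]})
        assert out.empty

    def test_shared_bin_averages_sessions(self):
        data = {
            "s1": [(12, 1.0), (55, 3.0)],
            "s2": [(18, 2.0), (52, 8.0)],
        }
        out = coding.condition_normalize_and_bin(data, bin_width=10)
        # both sessions are z-scored to (-1, 1); both contribute to bins 1 and 5
        row = out[out["bin"] == 5].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["count"] == 2

    def test_sessions_contribute_only_sampled_bins(self):
        data = {"low": [(5, 1.0), (15, 2.0)], "high": [(85, 1.0), (95, 2.0)]}
        out = coding.condition_normalize_and_bin(data, bin_width=10)
        assert set(out["bin"]) == {0, 1, 8, 9}


class TestPupilContrasts:
    def _sessions(self, effect):
        rng = np.random.default_rng(0)
        out = {}
        for k in range(8):
            centers = np.linspace(12, 88, 10)
            vals = 0.4 + 0.02 * rng.normal(size=10)
            if effect:
                vals += 0.1 * np.exp(-((centers - 50) / 25) ** 2)
            out[k] = (centers, vals)
        return out

    def test_inverted_u_gives_positive_contrasts(self):
        data = self._sessions(effect=True)
        d_low, p_low = coding.central_vs_extreme_deciles(data, "low")
        d_high, p_high = coding.central_vs_extreme_deciles(data, "high")
        assert (d_low > 0).mean() > 0.7
        assert (d_high > 0).mean() > 0.7
        assert p_low < 0.05 and p_high < 0.05

    def test_sessions_without_constricted_pupil_excluded(self):
        data = {0: (np.linspace(40, 90, 10), np.full(10, 0.4))}
        d, p = coding.central_vs_extreme_deciles(data, "low")
        assert len(d) == 0 and np.isnan(p)

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            coding.central_vs_extreme_deciles(self._sessions(False), "mid")
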