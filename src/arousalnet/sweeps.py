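"""Arousal-modulation sweeps: simulate, analyze, and tabulate.

These workflows tie the simulator to the analysis modules: for each value of
the input-heterogeneity modulation and each network realization they run
evoked (and optionally spontaneous-only) trials and compute decoding
accuracy, single-cell discriminability, cluster-dynamics statistics, Fano
factors, and low-frequency spectral power. Problem sizes default to the
reduced network configuration.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clusters as cl
from . import coding, variability
from .network import (assign_external_rates, build_clustered, build_uniform,
                      make_stimulus_set)
from .params import ArousalModulation, SimConfig, default_config
from .simulate import run_experiment

__all__ = ["sweep_realization", "arousal_sweep", "session_pupil_decoding",
           "session_modulation_fractions"]


def _spectra_p_low(ts, rate_floor: float = 1.0, band=(1.0, 4.0)):
    """Cell-averaged low-frequency power over E cells above the rate floor."""
    e_cells = np.flatnonzero(ts.unit_pop == 0)
    by_unit = {u: [] for u in e_cells}
    for tid, stim, units, times in ts.trials():
        sel = np.isin(units, e_cells)
        for u in e_cells:
            by_unit[u].append(times[units == u])
    vals = []
    for u, trains in by_unit.items():
        total = sum(len(t) for t in trains)
        if total / (len(trains) * ts.duration) < rate_floor:
            continue
        est = variability.multitaper_point_spectrum(trains, ts.duration)
        vals.append(variability.low_freq_power(est, band))
    return float(np.mean(vals)) if vals else float("nan")


def _fano_summary(count_mat: coding.CountMatrix, ts, stimuli, rate_floor=1.0):
    """Population-averaged spontaneous/evoked FF over cells in stimulated
    clusters (per stimulus, then averaged across stimuli)."""
    ffs, ffe = [], []
    pre_dur = ts.t_stim
    for s in stimuli:
        tr_sel = count_mat.labels == s.stim_id
        if tr_sel.sum() < 2:
            continue
        cells = np.isin(count_mat.unit_ids, s.targeted_cells)
        X = count_mat.counts[tr_sel][:, cells, :]
        # rate floor on pre-stimulus windows
        pre = count_mat.window_centers + count_mat.window / 2 <= 1e-9
        rate = X[:, :, pre].mean(axis=(0, 2)) / count_mat.window
        X = X[:, rate >= rate_floor, :]
        if X.shape[1] == 0:
            continue
        est = variability.fano_timecourse(X, count_mat.window_centers,
                                          window=count_mat.window)
        ffs.append(np.nanmean(est.ff_spont))
        ffe.append(np.nanmean(est.ff_evoked))
    if not ffs:
        return float("nan"), float("nan")
    return float(np.mean(ffs)), float(np.mean(ffe))


def sweep_realization(arch, neuron, stim_cfg: dict, dh_grid: Sequence[float],
                      realization_seed: int, clustered: bool = True,
                      n_trials: int = 15, trial_duration: float = 1.7,
                      t_stim: float = 1.0, dt: float = 1e-4,
                      decode_runs: int = 8, decode_repeats: int = 3,
                      with_spont: bool = True, n_spont_trials: int = 10,
                      spont_duration: float = 2.5,
                      with_cluster_metrics: bool = True) -> pd.DataFrame:
    """Run one network realization across the modulation grid and return a
    tidy table of summary metrics (one row per modulation value)."""
    rng = np.random.default_rng(realization_seed)
    net_seed = int(rng.integers(2**31))
    z_seed = int(rng.integers(2**31))
    build = build_clustered if clustered else build_uniform
    inst = build(arch, neuron, seed=net_seed)
    stimuli = make_stimulus_set(
        inst, n_stimuli=stim_cfg.get("n_stimuli", 5),
        frac_clusters=stim_cfg.get("frac_clusters", 0.5),
        frac_cells=stim_cfg.get("frac_cells", 0.5),
        seed=int(rng.integers(2**31)), A_stim_E=stim_cfg.get("A_stim_E", 0.07),
        tau_r=stim_cfg.get("tau_r", 0.05), tau_d=stim_cfg.get("tau_d", 0.15),
        t_stim=t_stim)
    rows = []
    for dh in dh_grid:
        mod = ArousalModulation(kind="heterogeneity", dH_E=float(dh), seed=z_seed)
        sc = SimConfig(dt=dt, trial_duration=trial_duration, t_stim=t_stim,
                       n_trials_per_stimulus=n_trials,
                       seed=int(rng.integers(2**31)))
        ts = run_experiment(inst, stimuli, sc, modulation=mod)
        row = dict(dh=float(dh), realization=realization_seed,
                   clustered=clustered)
        # mean spontaneous E rate
        spont_mask = ts.spikes["time_s"] < t_stim
        e_mask = ts.unit_pop[ts.spikes["unit_id"]] == 0
        n_e = (ts.unit_pop == 0).sum()
        row["e_rate_spont"] = float((spont_mask & e_mask).sum()
                                    / (ts.n_trials * t_stim * n_e))
        # decoding (p+1-feature subsamples) and d' (all E cells)
        dec = coding.model_feature_sample(ts, n_runs=decode_runs,
                                          seed=int(rng.integers(2**31)),
                                          n_repeats=decode_repeats)
        row["peak_accuracy"] = dec.peak_accuracy
        e_cells = np.flatnonzero(ts.unit_pop == 0)
        cm = coding.sliding_counts(ts, units=e_cells)
        row["dsc_prime"] = coding.dprime_pipeline(cm).Dsc_prime
        # Fano factors (cells in stimulated clusters, 200 ms evoked scan)
        cm_ff = coding.sliding_counts(ts, span=(-0.2, 0.3), units=e_cells)
        row["ff_spont"], row["ff_evoked"] = _fano_summary(cm_ff, ts, stimuli)
        row["delta_ff"] = row["ff_spont"] - row["ff_evoked"]
        if clustered and with_cluster_metrics:
            traces = list(cl.trial_cluster_traces(ts))
            summ = cl.activation_summary(traces, window=(-0.8, -0.1), t_stim=t_stim)
            row["nA_star"] = summ.nA_star
            # unconditioned active/inactive rates in the pre-stimulus window
            ups, dns = [], []
            for tr in traces:
                m = (tr.time >= t_stim - 0.8) & (tr.time < t_stim - 0.1)
                act, _ = cl.activation_states(tr)
                r = tr.rates[:, m]
                a = act[:, m]
                if a.any():
                    ups.append(r[a].mean())
                dns.append(r[~a].mean())
            row["r_active"] = float(np.mean(ups)) if ups else float("nan")
            row["r_inactive"] = float(np.mean(dns))
            row["rate_gap"] = row["r_active"] - row["r_inactive"]
            row["timescale"] = cl.activation_timescale(traces, window=(-0.8, -0.1),
                                                       t_stim=t_stim)
            w0 = dec.window_centers[dec.peak_window] - 0.05
            ev = cl.evoked_cluster_metrics(traces, stimuli,
                                           peak_window=(w0, w0 + 0.1),
                                           t_stim=t_stim)
            row["Cs"] = ev.Cs
            row["Cr"] = ev.Cr
            row["delta_tau"] = ev.delta_tau
        if with_spont:
            sc_sp = SimConfig(dt=dt, trial_duration=spont_duration,
                              t_stim=spont_duration,
                              seed=int(rng.integers(2**31)))
            ts_sp = run_experiment(inst, [], sc_sp, modulation=mod,
                                   spontaneous_only=True,
                                   spontaneous_duration=spont_duration,
                                   n_spontaneous_trials=n_spont_trials)
            row["p_low"] = _spectra_p_low(ts_sp)
        rows.append(row)
    return pd.DataFrame(rows)


def session_pupil_decoding(sess, window: float = 0.1, step: float = 0.02,
                           span=(-0.1, 0.6), n_repeats: int = 3,
                           n_folds: int = 5, seed: int = 0):
    """Tone decoding per pupil decile for a (synthetic) session.

    Trials are aligned to tone onsets, counts taken in sliding windows,
    trials split into pupil deciles by the mean pupil over the 100 ms before
    onset (balanced per tone within each decile), and the peak decoding
    accuracy computed independently per decile. Returns (decile pupil
    centers, peak accuracy per decile).
    """
    from .session import pupil_decile_partition

    rng = np.random.default_rng(seed)
    ev = sess.events
    onsets = ev["time"].to_numpy()
    labels = ev["stim_id"].to_numpy()
    pupil = np.array([sess.pupil_in(t - 0.1, t) for t in onsets])
    ok = np.isfinite(pupil)
    onsets, labels, pupil = onsets[ok], labels[ok], pupil[ok]
    starts = np.arange(span[0], span[1] - window + 1e-9, step)
    centers = starts + window / 2
    counts = np.zeros((len(onsets), sess.n_units, len(starts)), dtype=np.int32)
    for u in range(sess.n_units):
        t = sess.unit_spikes(u)
        for k, on in enumerate(onsets):
            i0 = np.searchsorted(t, on + starts)
            i1 = np.searchsorted(t, on + starts + window)
            counts[k, u] = i1 - i0
    parts, pup_centers = pupil_decile_partition(pupil, labels=labels, rng=rng)
    accs = []
    for part in parts:
        cm = coding.CountMatrix(counts=counts[part], labels=labels[part],
                                window_centers=centers, window=window,
                                step=step, unit_ids=np.arange(sess.n_units))
        res = coding.decode_timecourse(cm, n_folds=n_folds, n_repeats=n_repeats,
                                       seed=int(rng.integers(2**31)))
        accs.append(res.peak_accuracy)
    return pup_centers, np.asarray(accs)


def session_modulation_fractions(sess, window: float = 0.1, seed: int = 0):
    """Fractions of units with significant positive/negative spontaneous
    rate-vs-pupil Spearman correlations over pupil deciles."""
    from .session import pupil_decile_partition, rate_arousal_classification

    starts, pupils = [], []
    for b0, b1, kind in sess.blocks:
        if kind != "spont":
            continue
        for s in np.arange(b0, b1 - window, window):
            m = sess.pupil_in(s, s + window)
            if np.isfinite(m):
                starts.append(s)
                pupils.append(m)
    starts = np.asarray(starts)
    pupils = np.asarray(pupils)
    parts, centers = pupil_decile_partition(pupils)
    rates = np.zeros((sess.n_units, 10))
    for u in range(sess.n_units):
        t = sess.unit_spikes(u)
        cnt = np.searchsorted(t, starts + window) - np.searchsorted(t, starts)
        for d, part in enumerate(parts):
            rates[u, d] = cnt[part].mean() / window
    cls = rate_arousal_classification(rates, centers)
    frac_pos = float((cls["cls"] == "positive").mean())
    frac_neg = float((cls["cls"] == "negative").mean())
    return cls, frac_pos, frac_neg


def arousal_sweep(dh_grid=(0.0, 0.1, 0.2, 0.3, 0.4), n_realizations: int = 3,
                  seed: int = 0, config: str = "reduced", clustered: bool = True,
                  **kwargs) -> pd.DataFrame:
    """Sweep the input-heterogeneity modulation over several network
    realizations (reduced-size network by default) and stack the per-
    realization summary tables."""
    cfg = default_config(config)
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_realizations):
        frames.append(sweep_realization(cfg["architecture"], cfg["neuron"],
                                        cfg["stimulus"], dh_grid,
                                        realization_seed=int(rng.integers(2**31)),
                                        clustered=clustered, **kwargs))
    return pd.concat(frames, ignore_index=True)
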