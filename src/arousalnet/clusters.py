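"""Cluster-level dynamics: activation states, nA statistics, timescales, and
evoked cluster signal/reliability.

Cluster firing rates are obtained by convolving member-cell spike trains with
a Gaussian kernel (default sigma = 25 ms) on a 1 ms grid and averaging across
the member cells; a cluster counts as *active* when its rate exceeds a fixed
threshold (default 15 spikes/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .simulate import TrialSet

__all__ = [
    "ClusterRateTrace",
    "ActivationSummary",
    "EvokedClusterMetrics",
    "cluster_rates",
    "trial_cluster_traces",
    "activation_states",
    "activation_summary",
    "activation_timescale",
    "evoked_cluster_metrics",
]

ACTIVATION_THRESHOLD = 15.0  # spikes/s


@dataclass
class ClusterRateTrace:
    """Smoothed firing rate of each cluster on a regular time grid."""

    rates: np.ndarray           # (n_clusters, n_bins), spikes/s
    time: np.ndarray            # bin centers (s)
    sigma: float
    step: float
    trial_id: int = 0
    stimulus: int = -1
    empty_clusters: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


@dataclass
class ActivationSummary:
    """Statistics of the number of simultaneously active clusters."""

    p_nA: np.ndarray            # P(nA), length p+1
    r_up: np.ndarray            # active-cluster rate conditioned on nA
    r_down: np.ndarray          # inactive-cluster rate conditioned on nA
    nA_star: int
    low_confidence: np.ndarray  # nA values with P(nA) < 0.1


@dataclass
class EvokedClusterMetrics:
    """Stimulus-evoked cluster statistics in the peak decoding window."""

    Cs: float                   # cluster signal (spikes/s)
    Cr: float                   # cluster reliability (fraction)
    f_in_T_spont: float
    f_in_T_evoked: float
    delta_tau: float            # targeted-vs-nontargeted activation-time diff


def cluster_rates(unit_ids: np.ndarray, times: np.ndarray, cluster_of: np.ndarray,
                  n_clusters: int, t_range, members_per_cluster: np.ndarray,
                  sigma: float = 0.025, step: float = 0.001) -> ClusterRateTrace:
    """Kernel-smoothed cluster firing rates for one trial.

    ``members_per_cluster`` gives the number of cells contributing to each
    cluster trace (the rate is the mean over member cells, which equals the
    smoothed pooled spike histogram divided by the member count).
    """
    t0, t1 = t_range
    nb = int(round((t1 - t0) / step))
    rates = np.zeros((n_clusters, nb))
    empties = []
    cl = cluster_of[unit_ids]
    for c in range(n_clusters):
        if members_per_cluster[c] == 0:
            empties.append(c)
            continue
        h, _ = np.histogram(times[cl == c], bins=nb, range=(t0, t1))
        rates[c] = gaussian_filter1d(h.astype(float), sigma / step,
                                     mode="constant") / (step * members_per_cluster[c])
    time = t0 + (np.arange(nb) + 0.5) * step
    return ClusterRateTrace(rates=rates, time=time, sigma=sigma, step=step,
                            empty_clusters=np.asarray(empties, int))


def trial_cluster_traces(ts: TrialSet, sigma: float = 0.025, step: float = 0.001,
                         t_range=None, pop: str = "E"):
    """Yield a :class:`ClusterRateTrace` per trial of a TrialSet (E cells)."""
    pop_code = 0 if pop == "E" else 1
    p = int(ts.unit_cluster[ts.unit_pop == pop_code].max())  # background = p
    members = np.array([np.sum((ts.unit_cluster == c) & (ts.unit_pop == pop_code))
                        for c in range(p)])
    if t_range is None:
        t_range = (0.0, ts.duration)
    for tid, stim, units, times in ts.trials():
        sel = ts.unit_pop[units] == pop_code
        trace = cluster_rates(units[sel], times[sel], ts.unit_cluster, p,
                              t_range, members, sigma=sigma, step=step)
        trace.trial_id, trace.stimulus = tid, int(stim)
        yield trace


def activation_states(trace: ClusterRateTrace, theta: float = ACTIVATION_THRESHOLD):
    """Boolean cluster-by-time activation matrix and its column sums nA(t)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    active = trace.rates >= theta
    return active, active.sum(axis=0)


def _window_mask(time: np.ndarray, window, t_ref: float):
    lo, hi = window
    return (time >= t_ref + lo) & (time < t_ref + hi)


def activation_summary(traces: Sequence[ClusterRateTrace], window=(-0.8, -0.1),
                       t_stim: float = 1.0, theta: float = ACTIVATION_THRESHOLD,
                       p_min: float = 0.1) -> ActivationSummary:
    """Pool pre-stimulus time points across trials and summarize P(nA) and the
    conditioned active/inactive cluster rates."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trial")
    p = traces[0].rates.shape[0]
    counts = np.zeros(p + 1)
    sum_up = np.zeros(p + 1)
    n_up = np.zeros(p + 1)
    sum_dn = np.zeros(p + 1)
    n_dn = np.zeros(p + 1)
    for tr in traces:
        m = _window_mask(tr.time, window, t_stim)
        if not m.any():
            raise ValueError("empty analysis window")
        act, nA = activation_states(tr, theta)
        act = act[:, m]
        nA = nA[:, None] if False else nA[m]
        r = tr.rates[:, m]
        for k in np.unique(nA):
            sel = nA == k
            counts[k] += sel.sum()
            if k > 0:
                # average over clusters first, then accumulate over time points
                up_mean = np.where(act[:, sel], r[:, sel], np.nan)
                sum_up[k] += np.nansum(np.nanmean(up_mean, axis=0))
                n_up[k] += sel.sum()
            if k < p:
                dn_mean = np.where(~act[:, sel], r[:, sel], np.nan)
                sum_dn[k] += np.nansum(np.nanmean(dn_mean, axis=0))
                n_dn[k] += sel.sum()
    p_nA = counts / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_up = sum_up / n_up
        r_down = sum_dn / n_dn
    return ActivationSummary(p_nA=p_nA, r_up=r_up, r_down=r_down,
                             nA_star=int(np.argmax(p_nA)),
                             low_confidence=np.flatnonzero(p_nA < p_min))


def _period_durations(active_row: np.ndarray, step: float):
    """Durations of contiguous True runs (window-clipped runs included)."""
    x = np.concatenate([[0], active_row.astype(int), [0]])
    d = np.diff(x)
    on = np.flatnonzero(d == 1)
    off = np.flatnonzero(d == -1)
    return (off - on) * step


def activation_timescale(traces: Sequence[ClusterRateTrace], window=(-0.8, -0.1),
                         t_stim: float = 1.0,
                         theta: float = ACTIVATION_THRESHOLD) -> float:
    """Mean duration of cluster activation periods: per-trial mean over all
    activation periods in the window, averaged over trials; NaN if no trial
    has any activation period."""
    per_trial = []
    for tr in traces:
        m = _window_mask(tr.time, window, t_stim)
        act, _ = activation_states(tr, theta)
        durs = np.concatenate([_period_durations(row[m], tr.step) for row in act])
        if len(durs):
            per_trial.append(durs.mean())
    return float(np.mean(per_trial)) if per_trial else float("nan")


def evoked_cluster_metrics(traces: Sequence[ClusterRateTrace], stimuli,
                           peak_window, t_stim: float = 1.0,
                           baseline_window=(-0.8, 0.0), spont_window=(-0.1, 0.0),
                           theta: float = ACTIVATION_THRESHOLD,
                           baseline_theta: float = 1.0,
                           persistence: float = 0.025) -> EvokedClusterMetrics:
    """Cluster signal, reliability and targeting statistics in the peak
    decoding window.

    ``peak_window`` is (start, end) in seconds relative to stimulus onset —
    normally the window of peak decoding accuracy. Baseline rates (per
    stimulus and cluster) are the time- and trial-averaged rates over the
    800 ms before onset; a cluster is "activated above baseline" when its
    baseline-subtracted rate exceeds ``baseline_theta`` (1 spike/s), and
    reliability additionally requires persistence for >= 25 ms.
    """
    traces = list(traces)
    targeted = {s.stim_id: set(int(c) for c in s.targeted_clusters) for s in stimuli}
    if any(len(v) == 0 for v in targeted.values()):
        raise ValueError("stimulus with zero targeted clusters")
    p = traces[0].rates.shape[0]
    step = traces[0].step
    n_persist = max(1, int(round(persistence / step)))

    # per-stimulus cluster baselines
    base = {}
    for sid in targeted:
        trs = [tr for tr in traces if tr.stimulus == sid]
        m = _window_mask(trs[0].time, baseline_window, t_stim)
        base[sid] = np.mean([tr.rates[:, m].mean(axis=1) for tr in trs], axis=0)

    cs_vals, cr_vals, dtau_vals, f_spont, f_evoked = [], [], [], [], []
    for tr in traces:
        sid = tr.stimulus
        if sid not in targeted:
            continue
        T = np.array([c in targeted[sid] for c in range(p)])
        mw = _window_mask(tr.time, peak_window, t_stim)
        r = tr.rates
        # cluster signal
        cs_vals.append(float(r[T][:, mw].mean() - r[~T][:, mw].mean()))
        # baseline-subtracted activation
        g = r - base[sid][:, None]
        act_base = g > baseline_theta
        sustained = np.zeros(p, bool)
        for c in range(p):
            durs = _period_durations(act_base[c, mw], step)
            sustained[c] = bool(len(durs)) and durs.max() >= persistence - 1e-12
        cr_vals.append(float(sustained[T].mean() - sustained[~T].mean()))
        # activation-time fractions
        tau = act_base[:, mw].mean(axis=1)
        dtau_vals.append(float(tau[T].mean() - tau[~T].mean()))
        # fraction of threshold-active clusters that are targeted
        act, nA = activation_states(tr, theta)
        with np.errstate(invalid="ignore"):
            frac_T = np.where(nA > 0, act[T].sum(axis=0) / np.maximum(nA, 1), np.nan)
        ms = _window_mask(tr.time, spont_window, t_stim)
        f_spont.append(np.nanmean(frac_T[ms]) if np.any(np.isfinite(frac_T[ms])) else np.nan)
        f_evoked.append(np.nanmean(frac_T[mw]) if np.any(np.isfinite(frac_T[mw])) else np.nan)

    def _nanmean(v):
        v = np.asarray(v, float)
        return float(np.nanmean(v)) if np.isfinite(v).any() else float("nan")

    return EvokedClusterMetrics(
        Cs=float(np.mean(cs_vals)), Cr=float(np.mean(cr_vals)),
        f_in_T_spont=_nanmean(f_spont), f_in_T_evoked=_nanmean(f_evoked),
        delta_tau=float(np.mean(dtau_vals)))
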