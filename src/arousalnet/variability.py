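"""Spiking variability: rate-normalized multitaper spectra and Fano factors.

Spectra follow the multitaper convention for point processes: spike trains
are binned at 1 ms, mean-subtracted (removing the DC rate line), tapered with
DPSS windows (time-bandwidth product TW = 5, 2*TW - 1 = 9 tapers), and the
taper- and trial-averaged spectrum is divided by the mean firing rate so that
a homogeneous Poisson process has unit power at all frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "SpectralEstimate",
    "FanoEstimate",
    "multitaper_point_spectrum",
    "low_freq_power",
    "fano_timecourse",
    "pupil_balanced_fano",
]


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    S_norm: np.ndarray
    n_tapers: int
    time_bandwidth: float
    n_trials: int
    n_excluded: int = 0

    def band_power(self, band=(1.0, 4.0)) -> float:
        return low_freq_power(self, band)


@dataclass
class FanoEstimate:
    ff: np.ndarray                # (units, windows)
    window_centers: np.ndarray    # s relative to onset
    ff_spont: np.ndarray          # per unit
    ff_evoked: np.ndarray         # per unit, at t_FFmin
    delta_ff: np.ndarray          # ff_spont - ff_evoked
    t_ffmin: float


def multitaper_point_spectrum(trains: Sequence[np.ndarray], trial_length: float,
                              TW: float = 5.0, n_tapers: Optional[int] = None,
                              bin_size: float = 0.001) -> SpectralEstimate:
    """Rate-normalized multitaper spectrum of a unit from repeated trials.

    ``trains`` is a sequence of spike-time arrays (seconds, one per trial).
    Trials without spikes are excluded (their rate normalization is
    undefined) and counted in ``n_excluded``.
    """
    if n_tapers is None:
        n_tapers = int(2 * TW - 1)
    nb = int(round(trial_length / bin_size))
    tapers = dpss(nb, TW, Kmax=n_tapers)          # unit-energy windows
    freqs = np.fft.rfftfreq(nb, d=bin_size)
    acc = np.zeros(len(freqs))
    used = 0
    excluded = 0
    for t in trains:
        t = np.asarray(t)
        t = t[(t >= 0) & (t < trial_length)]
        if len(t) == 0:
            excluded += 1
            continue
        x, _ = np.histogram(t, bins=nb, range=(0.0, trial_length))
        xc = x - x.mean()
        X = np.fft.rfft(tapers * xc[None, :], axis=1)
        S = (np.abs(X) ** 2).mean(axis=0) / bin_size
        rate = len(t) / trial_length
        acc += S / rate
        used += 1
    if used == 0:
        raise ValueError("no trials with spikes")
    return SpectralEstimate(freqs=freqs, S_norm=acc / used, n_tapers=n_tapers,
                            time_bandwidth=TW, n_trials=used, n_excluded=excluded)


def low_freq_power(estimate: SpectralEstimate, band=(1.0, 4.0)) -> float:
    """Mean of the normalized spectrum over grid frequencies in ``band``
    (endpoints inclusive; excludes f = 0)."""
    lo, hi = band
    sel = (estimate.freqs >= lo - 1e-12) & (estimate.freqs <= hi + 1e-12) & (estimate.freqs > 0)
    if not sel.any():
        raise ValueError("band contains no frequency grid points")
    return float(estimate.S_norm[sel].mean())


def fano_timecourse(counts: np.ndarray, window_centers: np.ndarray,
                    window: float = 0.1, evoked_limit: float = 0.2) -> FanoEstimate:
    """Fano factor (across-trial variance/mean of spike counts) per unit and
    window.

    ``counts`` has shape (trials, units, windows) with ``window_centers``
    relative to stimulus onset. The spontaneous FF is taken from the window
    immediately preceding onset; the evoked FF is read at the time of the
    minimum of the population-averaged FF within ``evoked_limit`` seconds
    after onset. Windows with zero mean count yield NaN.
    """
    counts = np.asarray(counts, float)
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    pre = np.flatnonzero(window_centers + window / 2 <= 1e-9)
    if len(pre) == 0:
        raise ValueError("no window fully precedes stimulus onset")
    i_spont = pre[-1]
    evoked = np.flatnonzero((window_centers > window / 2 - 1e-9)
                            & (window_centers <= evoked_limit + window / 2 + 1e-9))
    if len(evoked) == 0:
        raise ValueError("no evoked windows within the scan limit")
    pop = np.nanmean(ff, axis=0)
    i_ev = evoked[np.nanargmin(pop[evoked])]
    return FanoEstimate(ff=ff, window_centers=window_centers,
                        ff_spont=ff[:, i_spont], ff_evoked=ff[:, i_ev],
                        delta_ff=ff[:, i_spont] - ff[:, i_ev],
                        t_ffmin=float(window_centers[i_ev]))


def pupil_balanced_fano(session, pupil_bins=(25, 35, 45, 55, 65, 75, 100),
                        n_subsamples: int = 100, window: float = 0.1,
                        min_windows: int = 25, rate_floor: float = 1.0,
                        seed: int = 0, units: Optional[np.ndarray] = None):
    """Spontaneous Fano factors per pupil-diameter bin with balanced sampling.

    The spontaneous blocks of a session are split into ``window``-long
    segments; each segment is assigned to a pupil bin (bin upper edges in %
    of maximum dilation). All bins are subsampled to the same number of
    segments, FFs are computed per unit and bin, and results are averaged over
    ``n_subsamples`` random subsamples. Units below ``rate_floor`` spikes/s in
    any bin are excluded. Returns (DataFrame with unit, bin, ff columns,
    per-bin segment count); raises if any bin has fewer than ``min_windows``
    segments.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    edges = np.asarray(pupil_bins, float)
    t0s, t1s = [], []
    for b0, b1, kind in session.blocks:
        if kind == "spont":
            t0s.append(b0)
            t1s.append(b1)
    seg_starts, seg_bins = [], []
    for b0, b1 in zip(t0s, t1s):
        starts = np.arange(b0, b1 - window + 1e-9, window)
        for s in starts:
            m = session.pupil_in(s, s + window)
            if np.isnan(m):
                continue
            seg_starts.append(s)
            seg_bins.append(int(np.searchsorted(edges, m, side="left")))
    seg_starts = np.asarray(seg_starts)
    seg_bins = np.asarray(seg_bins)
    n_bins = len(edges)
    per_bin = [np.flatnonzero(seg_bins == b) for b in range(n_bins)]
    n_min = min(len(ix) for ix in per_bin)
    if n_min < min_windows:
        raise ValueError(f"a pupil bin has only {n_min} windows "
                         f"(< {min_windows}); session excluded")
    if units is None:
        units = np.arange(session.n_units)
    # spike counts per unit per segment
    counts = np.zeros((len(units), len(seg_starts)), dtype=np.int32)
    for iu, u in enumerate(units):
        t = session.unit_spikes(u)
        idx0 = np.searchsorted(t, seg_starts)
        idx1 = np.searchsorted(t, seg_starts + window)
        counts[iu] = idx1 - idx0
    # rate floor per bin
    mean_rate = np.stack([counts[:, ix].mean(axis=1) / window for ix in per_bin])
    keep = (mean_rate >= rate_floor).all(axis=0)
    rows = []
    ff_acc = np.zeros((keep.sum(), n_bins))
    for _ in range(n_subsamples):
        for b in range(n_bins):
            ix = rng.choice(per_bin[b], size=n_min, replace=False)
            c = counts[keep][:, ix].astype(float)
            m = c.mean(axis=1)
            v = c.var(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ff_acc[:, b] += np.where(m > 0, v / m, np.nan)
    ff_acc /= n_subsamples
    kept_units = units[keep]
    for iu, u in enumerate(kept_units):
        for b in range(n_bins):
            rows.append(dict(unit=int(u), bin=b, bin_edge=edges[b],
                             ff=ff_acc[iu, b]))
    return pd.DataFrame(rows), n_min
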