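"""Synthetic extracellular sessions and pupillometry-side preprocessing.

The generator emulates the structure of an awake head-fixed recording:
alternating spontaneous and tone-presentation blocks (25 ms tones from five
frequencies, 775 ms inter-stimulus interval), a slow mean-reverting pupil
trace sampled at 30 Hz and upsampled to 1 ms, a treadmill-speed trace at
100 Hz, doubly-stochastic spiking whose spontaneous and evoked rates depend
on pupil through per-unit gain curves (monotone up/down, inverted-U, or
flat), and per-spike template amplitudes with optional injected quality
defects. Ground-truth generative parameters are stored for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "PupilTrace",
    "SessionConfig",
    "SyntheticSession",
    "QCReport",
    "generate_session",
    "clean_pupil",
    "unit_qc",
    "tone_responsiveness",
    "pupil_decile_partition",
    "rate_arousal_classification",
]

TONE_FREQS_KHZ = (2.0, 4.0, 8.0, 16.0, 32.0)
TONE_DURATION = 0.025
TONE_ISI = 0.775


@dataclass
class PupilTrace:
    """Pupil diameter at 1 ms resolution, in % of session maximum."""

    time: np.ndarray
    diameter: np.ndarray
    valid: np.ndarray


@dataclass
class SessionConfig:
    n_units: int = 40
    spont_block: float = 60.0       # s per spontaneous block
    evoked_block: float = 240.0     # s per evoked block
    n_block_pairs: int = 1
    gain_shape_fractions: dict = field(default_factory=lambda: dict(
        up=0.3, down=0.3, inverted_u=0.2, flat=0.2))
    gain_strength: float = 0.8      # relative modulation depth of gain curves
    evoked_gain_follows_pupil: bool = True
    pupil_tau: float = 20.0         # s, mean reversion
    pupil_sigma: float = 0.18       # stationary s.d. (fraction of range)
    slow_noise_sigma: float = 0.3   # doubly-stochastic log-rate s.d.
    slow_noise_tau: float = 0.5     # s
    low_pupil_slow_noise: bool = False  # extra slow rate noise at low pupil
    artifact_rate: float = 0.0      # pupil jump artifacts per minute
    frac_bimodal_units: float = 0.0
    frac_drift_units: float = 0.0
    base_rate_lognorm: tuple = (1.3, 0.6)  # ln-mean, ln-sd of spont rates


@dataclass
class SyntheticSession:
    config: SessionConfig
    seed: int
    duration: float
    blocks: list                       # (t0, t1, 'spont'|'evoked')
    pupil: PupilTrace
    pupil_raw: np.ndarray              # before cleaning, normalized to max
    running: np.ndarray                # cm/s at 100 Hz
    events: pd.DataFrame               # time, freq_khz, stim_id
    spikes: list                       # per-unit spike-time arrays
    amplitudes: list                   # per-unit (times, amps)
    ground_truth: dict

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    def unit_spikes(self, u: int) -> np.ndarray:
        return self.spikes[u]

    def pupil_in(self, t0: float, t1: float) -> float:
        i0, i1 = int(t0 * 1000), int(t1 * 1000)
        d = self.pupil.diameter[i0:i1]
        v = self.pupil.valid[i0:i1]
        if v.sum() == 0:
            return float("nan")
        return float(d[v].mean())


@dataclass
class QCReport:
    unit: int
    keep: bool
    reasons: list
    window_flags: dict


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _gain(shape: str, pupil_pct: np.ndarray, strength: float) -> np.ndarray:
    x = pupil_pct / 100.0
    if shape == "up":
        return 1.0 + strength * (x - 0.5)
    if shape == "down":
        return 1.0 - strength * (x - 0.5)
    if shape == "inverted_u":
        return 1.0 + strength * (0.5 - 2.0 * np.abs(x - 0.5)) * 2.0
    return np.ones_like(x)


def generate_session(config: SessionConfig, seed: int = 0) -> SyntheticSession:
    """Generate one synthetic session; see the module docstring."""
    rng = np.random.default_rng(seed)
    cfg = config
    blocks = []
    t = 0.0
    for _ in range(cfg.n_block_pairs):
        blocks.append((t, t + cfg.spont_block, "spont"))
        t += cfg.spont_block
        blocks.append((t, t + cfg.evoked_block, "evoked"))
        t += cfg.evoked_block
    duration = t
    if duration <= 0:
        raise ValueError("infeasible schedule: zero-length session")
    n_ms = int(round(duration * 1000))

    # pupil: OU at 30 Hz + dilation events, upsampled to 1 ms
    n30 = int(duration * 30) + 2
    dt30 = 1.0 / 30
    x = np.zeros(n30)
    x[0] = rng.normal(0, cfg.pupil_sigma)
    drive = np.zeros(n30)
    n_events = rng.poisson(duration / 40.0)
    for te in rng.uniform(0, duration, n_events):
        k = int(te * 30)
        drive[k:k + int(30 * 5)] += rng.uniform(0.2, 0.5)
    a = np.exp(-dt30 / cfg.pupil_tau)
    sig_step = cfg.pupil_sigma * np.sqrt(1 - a ** 2)
    for k in range(1, n30):
        x[k] = a * x[k - 1] + (1 - a) * drive[k] + sig_step * rng.normal()
    raw30 = 0.5 + x
    t30 = np.arange(n30) * dt30
    tms = np.arange(n_ms) / 1000.0
    raw = np.interp(tms, t30, raw30)
    raw = np.clip(raw, 0.02, None)
    # injected jump artifacts
    artifact_times = np.sort(rng.uniform(0, duration,
                                         rng.poisson(cfg.artifact_rate * duration / 60)))
    for ta in artifact_times:
        k = int(ta * 1000)
        raw[k:k + int(rng.uniform(0.05, 0.2) * 1000)] += rng.choice([-1, 1]) * rng.uniform(0.15, 0.3)
    raw = np.clip(raw, 0.01, None)
    raw_norm = raw / raw.max()
    pupil = clean_pupil(raw_norm)

    # running: bouts at 100 Hz
    n100 = int(duration * 100)
    running = np.zeros(n100)
    n_bouts = rng.poisson(duration / 60.0)
    for tb in rng.uniform(0, duration, n_bouts):
        k = int(tb * 100)
        length = int(rng.uniform(2, 10) * 100)
        running[k:k + length] = rng.uniform(2, 15)

    # tone schedule
    ev_rows = []
    for b0, b1, kind in blocks:
        if kind != "evoked":
            continue
        te = b0 + 0.5
        while te + TONE_DURATION + TONE_ISI < b1:
            sid = int(rng.integers(len(TONE_FREQS_KHZ)))
            ev_rows.append((te, TONE_FREQS_KHZ[sid], sid))
            te += TONE_DURATION + TONE_ISI
    events = pd.DataFrame(ev_rows, columns=["time", "freq_khz", "stim_id"])

    # unit properties
    shapes = list(cfg.gain_shape_fractions)
    probs = np.array([cfg.gain_shape_fractions[s] for s in shapes], float)
    probs = probs / probs.sum()
    unit_shape = rng.choice(shapes, size=cfg.n_units, p=probs)
    base_rate = rng.lognormal(*cfg.base_rate_lognorm, size=cfg.n_units)
    pref = rng.integers(0, len(TONE_FREQS_KHZ), size=cfg.n_units)
    tuning_width = rng.uniform(0.8, 1.6, size=cfg.n_units)  # octaves
    ev_amp = rng.uniform(2.0, 5.0, size=cfg.n_units)        # evoked gain multiple
    n_bim = int(round(cfg.frac_bimodal_units * cfg.n_units))
    n_drift = int(round(cfg.frac_drift_units * cfg.n_units))
    defect = np.array(["none"] * cfg.n_units, dtype=object)
    order = rng.permutation(cfg.n_units)
    for u in order[:n_bim]:
        defect[u] = "bimodal"
    for u in order[n_bim:n_bim + n_drift]:
        defect[u] = "drift"

    pupil_ms = pupil.diameter  # % max on 1 ms grid
    # evoked kernel on 1 ms grid (alpha-like, ~10 ms rise / 50 ms decay)
    tk = np.arange(0, 200) / 1000.0
    kernel = (np.exp(-tk / 0.05) - np.exp(-tk / 0.01))
    kernel /= kernel.max()

    log2f = np.log2(np.array(TONE_FREQS_KHZ))
    spikes, amplitudes = [], []
    for u in range(cfg.n_units):
        g = _gain(unit_shape[u], pupil_ms, cfg.gain_strength)
        # slow multiplicative rate noise (doubly stochastic)
        nslow = int(duration / cfg.slow_noise_tau) + 2
        z = rng.normal(0, 1, nslow)
        slow = np.interp(tms, np.arange(nslow) * cfg.slow_noise_tau, z)
        sigma_slow = cfg.slow_noise_sigma * np.ones(n_ms)
        if cfg.low_pupil_slow_noise:
            sigma_slow = cfg.slow_noise_sigma * (1.6 - 1.2 * pupil_ms / 100.0)
        rate = base_rate[u] * g * np.exp(sigma_slow * slow - sigma_slow ** 2 / 2)
        # evoked responses
        ev_rate = np.zeros(n_ms)
        for te, fk, sid in events.itertuples(index=False):
            k = int(te * 1000)
            tune = np.exp(-0.5 * ((log2f[sid] - log2f[pref[u]]) / tuning_width[u]) ** 2)
            gain_ev = (_gain(unit_shape[u], np.array([pupil_ms[k]]), cfg.gain_strength)[0]
                       if cfg.evoked_gain_follows_pupil else 1.0)
            ev_rate[k:k + len(kernel)] += base_rate[u] * ev_amp[u] * tune * gain_ev * kernel[:max(0, min(len(kernel), n_ms - k))]
        lam = (rate + ev_rate) / 1000.0
        n_sp = rng.poisson(lam)
        idx = np.repeat(np.arange(n_ms), n_sp)
        st = (idx + rng.random(len(idx))) / 1000.0
        st = np.sort(st)
        spikes.append(st)
        # template amplitudes
        a0 = rng.uniform(8.0, 20.0)
        amp = a0 * (1 + 0.04 * rng.normal(size=len(st)))
        if defect[u] == "bimodal":
            sel = rng.random(len(st)) < 0.5
            amp[sel] *= 1.9
        elif defect[u] == "drift":
            amp *= np.clip(1.0 - 0.9 * (st / duration), 0.12, None)
        amplitudes.append((st, amp))

    gt = dict(unit_shape=unit_shape, base_rate=base_rate, pref=pref,
              defect=defect, artifact_times=artifact_times, ev_amp=ev_amp)
    return SyntheticSession(config=cfg, seed=seed, duration=duration,
                            blocks=blocks, pupil=pupil, pupil_raw=raw_norm,
                            running=running, events=events, spikes=spikes,
                            amplitudes=amplitudes, ground_truth=gt)


# ---------------------------------------------------------------------------
# pupil preprocessing
# ---------------------------------------------------------------------------

def clean_pupil(raw: np.ndarray, jump_threshold: float = 0.08,
                mask_before: float = 0.25, mask_after: float = 0.5,
                smooth_window: float = 1.0 / 30) -> PupilTrace:
    """Artifact removal, smoothing, and renormalization of a raw pupil trace.

    ``raw`` is sampled at 1 ms and normalized to its maximum. Samples whose
    normalized diameter jumps by more than ``jump_threshold`` between
    consecutive samples are masked together with the surrounding
    [-250, +500] ms; the trace is then smoothed by a moving average of
    1/30 s and renormalized so the maximum is 100%.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    valid = np.ones(n, dtype=bool)
    jumps = np.flatnonzero(np.abs(np.diff(raw)) > jump_threshold)
    nb, na = int(mask_before * 1000), int(mask_after * 1000)
    for j in jumps:
        valid[max(0, j - nb): j + na] = False
    if not valid.any():
        raise ValueError("entire pupil trace masked as artifact")
    filled = raw.copy()
    if (~valid).any():
        good = np.flatnonzero(valid)
        filled[~valid] = np.interp(np.flatnonzero(~valid), good, raw[good])
    w = max(1, int(round(smooth_window * 1000)))
    kernel = np.ones(w) / w
    sm = np.convolve(filled, kernel, mode="same")
    sm = 100.0 * sm / sm[valid].max()
    return PupilTrace(time=np.arange(n) / 1000.0, diameter=sm, valid=valid)


# ---------------------------------------------------------------------------
# unit quality control
# ---------------------------------------------------------------------------

def _pdf_peaks(amps: np.ndarray, grid: np.ndarray):
    kde = stats.gaussian_kde(amps)  # Scott's rule bandwidth
    pdf = kde(grid)
    pk, props = find_peaks(pdf, height=pdf.max() * 1e-3)
    heights = pdf[pk]
    order = np.argsort(heights)[::-1]
    return grid[pk][order], heights[order]


def _pct_diff(a: float, b: float) -> float:
    return 200.0 * abs(a - b) / (abs(a) + abs(b))


def unit_qc(spike_times: np.ndarray, amp_times: np.ndarray, amps: np.ndarray,
            duration: float, window: float = 300.0, rate_floor: float = 0.25,
            peak_ratio_cut: float = 10.0, peak_sep_cut: float = 40.0,
            frac_cut: float = 0.1, floor_prox_cut: float = 15.0,
            drift_range_cut: float = 25.0, unit: int = 0) -> QCReport:
    """Keep/reject decision for one unit from its firing rate and the shape
    of its template-amplitude distribution in non-overlapping 5-minute
    windows (kernel density estimate, Gaussian kernel, Scott's rule).

    Rejection reasons: overall rate below 0.25 spikes/s; multimodal amplitude
    distributions (peak-height ratio <= 10 and peak-location percent
    difference >= 40) in at least 10% of windows; drift toward/away from the
    noise floor (>10% but not all windows with the main peak within 15% of
    the floor, and a max peak-location spread >= 25%).
    """
    reasons = []
    flags = dict(multimodal=[], near_floor=[], main_peak=[])
    rate = len(spike_times) / duration
    if rate < rate_floor:
        reasons.append("low_rate")
    n_win = int(np.ceil(duration / window))
    if len(amps) < 10 or n_win < 1:
        return QCReport(unit=unit, keep=not reasons, reasons=reasons + ["insufficient_data"],
                        window_flags=flags)
    floor = float(np.min(amps))
    grid = np.linspace(amps.min() * 0.5, amps.max() * 1.2, 512)
    main_locs = []
    for k in range(n_win):
        sel = (amp_times >= k * window) & (amp_times < (k + 1) * window)
        a = amps[sel]
        if len(a) < 10 or np.ptp(a) == 0:
            continue
        locs, hts = _pdf_peaks(a, grid)
        if len(locs) == 0:
            continue
        main_locs.append(locs[0])
        multi = False
        if len(locs) > 1:
            ratio = hts[0] / hts[1]
            sep = _pct_diff(locs[0], locs[1])
            multi = (ratio <= peak_ratio_cut) and (sep >= peak_sep_cut)
        flags["multimodal"].append(multi)
        flags["near_floor"].append(_pct_diff(locs[0], floor) <= floor_prox_cut)
        flags["main_peak"].append(locs[0])
    n_eval = len(flags["multimodal"])
    if n_eval:
        if np.mean(flags["multimodal"]) >= frac_cut:
            reasons.append("multimodal_amplitude")
        frac_floor = np.mean(flags["near_floor"])
        if n_eval > 1 and 0 < frac_floor < 1 and frac_floor > frac_cut:
            spread = _pct_diff(max(main_locs), min(main_locs))
            if spread >= drift_range_cut:
                reasons.append("noise_floor_drift")
    return QCReport(unit=unit, keep=len(reasons) == 0, reasons=reasons,
                    window_flags=flags)


# ---------------------------------------------------------------------------
# tone responsiveness
# ---------------------------------------------------------------------------

def tone_responsiveness(spike_times: np.ndarray, events: pd.DataFrame,
                        window: float = 0.1, step: float = 0.001,
                        evoked_period: float = 0.2, baseline_period: float = 0.2,
                        alpha: float = 0.05, min_run: int = 5) -> dict:
    """Per-tone responsiveness of one unit.

    For each tone, sliding-window counts (100 ms, 1 ms steps) in the 200 ms
    after onset are compared against the pooled counts of all baseline
    windows fully inside the 200 ms before onset (Mann-Whitney U test,
    Bonferroni-corrected over evoked windows); the unit is responsive to the
    tone if the corrected p-value stays below ``alpha`` for at least
    ``min_run`` consecutive steps.
    """
    out = {}
    t = np.asarray(spike_times)
    for sid, ev in events.groupby("stim_id"):
        onsets = ev["time"].to_numpy()
        if len(onsets) < 2:
            out[int(sid)] = False
            continue
        # counts per trial for every 1 ms-stepped window in [-base, evoked]
        starts = np.arange(-baseline_period, evoked_period - window + step / 2, step)
        n_w = len(starts)
        cnt = np.zeros((len(onsets), n_w), dtype=np.int32)
        for i, on in enumerate(onsets):
            lo = np.searchsorted(t, on + starts[0])
            hi = np.searchsorted(t, on + starts[-1] + window)
            rel = t[lo:hi] - on
            i0 = np.searchsorted(rel, starts)
            i1 = np.searchsorted(rel, starts + window)
            cnt[i] = i1 - i0
        base_mask = starts + window <= 1e-12
        ev_mask = starts + window > 1e-12  # windows ending in the evoked period
        baseline = cnt[:, base_mask].ravel()
        n_ev = ev_mask.sum()
        sig = np.zeros(n_ev, dtype=bool)
        if baseline.size == 0:
            raise ValueError("no baseline windows")
        for k, wi in enumerate(np.flatnonzero(ev_mask)):
            x = cnt[:, wi]
            if x.max() == 0 and baseline.max() == 0:
                continue
            p = stats.mannwhitneyu(x, baseline, alternative="two-sided").pvalue
            sig[k] = (p * n_ev) < alpha
        # longest run of consecutive significant windows
        run, best = 0, 0
        for s in sig:
            run = run + 1 if s else 0
            best = max(best, run)
        out[int(sid)] = best >= min_run
    return out


# ---------------------------------------------------------------------------
# arousal partitioning and classification
# ---------------------------------------------------------------------------

def pupil_decile_partition(pupil_values: np.ndarray, labels: Optional[np.ndarray] = None,
                           running_flags: Optional[np.ndarray] = None,
                           rng: Optional[np.random.Generator] = None):
    """Split trials/windows into ten partitions by pupil-diameter deciles.

    With ``labels`` given, each partition is subsampled so it holds the same
    number of items per label. Items flagged in ``running_flags`` (locomotion)
    are excluded beforehand. Returns (list of 10 index arrays, decile mean
    pupil per partition).
    """
    pupil_values = np.asarray(pupil_values, float)
    idx = np.arange(len(pupil_values))
    if running_flags is not None:
        idx = idx[~np.asarray(running_flags, bool)]
    if len(idx) < 10:
        raise ValueError("too few items for a decile partition")
    vals = pupil_values[idx]
    if np.ptp(vals) == 0:
        raise ValueError("degenerate pupil distribution (all values equal)")
    order = np.argsort(vals, kind="stable")
    parts = [idx[order[len(order) * k // 10: len(order) * (k + 1) // 10]]
             for k in range(10)]
    if labels is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        labels = np.asarray(labels)
        balanced = []
        for part in parts:
            lab = labels[part]
            classes, cnts = np.unique(lab, return_counts=True)
            n = cnts.min() if len(classes) else 0
            keep = [rng.choice(part[lab == c], size=n, replace=False)
                    for c in classes]
            balanced.append(np.sort(np.concatenate(keep)) if keep else part[:0])
        parts = balanced
    centers = [float(pupil_values[p].mean()) if len(p) else float("nan") for p in parts]
    return parts, np.asarray(centers)


def rate_arousal_classification(rates: np.ndarray, condition: np.ndarray,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation between per-unit rates and an arousal coordinate.

    ``rates`` is (units, conditions) — e.g. mean rate per pupil decile, or
    trial-averaged rate per modulation strength — and ``condition`` the
    matching arousal values. Returns a frame with unit, r, p and class in
    {positive, negative, none}.
    """
    rates = np.atleast_2d(np.asarray(rates, float))
    condition = np.asarray(condition, float)
    if rates.shape[1] != len(condition):
        raise ValueError("rates and condition length mismatch")
    if len(condition) < 3:
        raise ValueError("need >= 3 conditions")
    rows = []
    for u in range(rates.shape[0]):
        r_u = rates[u]
        if np.ptp(r_u) == 0 or np.any(~np.isfinite(r_u)):
            rows.append(dict(unit=u, r=np.nan, p=np.nan, cls="none"))
            continue
        r, p = stats.spearmanr(r_u, condition)
        cls = "none"
        if np.isfinite(p) and p < alpha:
            cls = "positive" if r > 0 else "negative"
        rows.append(dict(unit=u, r=r, p=p, cls=cls))
    return pd.DataFrame(rows)
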