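"""Population decoding and single-cell discriminability.

Decoding uses a multiclass linear discriminant (shared within-class
covariance, sklearn's LDA with the 'svd' solver) on sliding-window spike
counts, with repeated stratified cross-validation; chance level for five
balanced stimuli is 0.2. Single-cell discriminability d' follows the pooled
standard-deviation convention
``d' = (mu_a - mu_b) / sqrt((sigma_a^2 + sigma_b^2) / 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .simulate import TrialSet

__all__ = [
    "CountMatrix",
    "DecodingResult",
    "DiscriminabilityResult",
    "sliding_counts",
    "balance_labels",
    "decode_timecourse",
    "shuffle_null",
    "model_feature_sample",
    "dprime_pipeline",
    "condition_normalize_and_bin",
    "central_vs_extreme_deciles",
]


@dataclass
class CountMatrix:
    """Sliding-window spike counts: (trials, units, windows)."""

    counts: np.ndarray
    labels: np.ndarray              # stimulus per trial
    window_centers: np.ndarray      # seconds relative to stimulus onset
    window: float
    step: float
    unit_ids: np.ndarray

    @property
    def n_trials(self):
        return self.counts.shape[0]


@dataclass
class DecodingResult:
    accuracy: np.ndarray            # per window
    peak_accuracy: float
    peak_window: int
    window_centers: np.ndarray
    n_folds: int
    n_repeats: int
    null_percentile: Optional[np.ndarray] = None


@dataclass
class DiscriminabilityResult:
    dprime_cell_time: np.ndarray    # (units, windows) pair-averaged d'
    dprime_time: np.ndarray         # cell-averaged timecourse
    Dsc_prime: float                # max over windows
    t_star: int
    dprime_cell_at_tstar: np.ndarray
    window_centers: np.ndarray


def sliding_counts(ts: TrialSet, window: float = 0.1, step: float = 0.02,
                   span=(-0.1, 0.6), units: Optional[np.ndarray] = None) -> CountMatrix:
    """Spike counts of each unit in sliding windows along each evoked trial.

    Windows start at ``span[0]`` (relative to onset) and advance by ``step``
    while they still fit inside the span.
    """
    lo, hi = span
    if hi - lo < window:
        raise ValueError("span shorter than window")
    starts = []
    s = lo
    while s + window <= hi + 1e-12:
        starts.append(s)
        s += step
    starts = np.asarray(starts)
    centers = starts + window / 2

    n_units_total = len(ts.unit_cluster)
    if units is None:
        units = np.arange(n_units_total)
    unit_pos = -np.ones(n_units_total, dtype=int)
    unit_pos[units] = np.arange(len(units))

    trials = list(ts.trials())
    counts = np.zeros((len(trials), len(units), len(starts)), dtype=np.int32)
    labels = np.empty(len(trials), dtype=int)
    for k, (tid, stim, uid, t) in enumerate(trials):
        labels[k] = stim
        rel = t - ts.t_stim
        pos = unit_pos[uid]
        ok = pos >= 0
        rel, pos = rel[ok], pos[ok]
        for wi, w0 in enumerate(starts):
            sel = (rel >= w0) & (rel < w0 + window)
            np.add.at(counts[k, :, wi], pos[sel], 1)
    return CountMatrix(counts=counts, labels=labels, window_centers=centers,
                       window=window, step=step, unit_ids=np.asarray(units))


def balance_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a random subsample with equal trial counts per label."""
    labels = np.asarray(labels)
    classes, cnts = np.unique(labels, return_counts=True)
    n = cnts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def _fit_predict_acc(Xtr, ytr, Xte, yte):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear count columns are routine
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(Xtr, ytr)
        return float((clf.predict(Xte) == yte).mean())


def decode_timecourse(counts: CountMatrix, n_folds: int = 5, n_repeats: int = 10,
                      seed: int = 0, balance: bool = True) -> DecodingResult:
    """Cross-validated decoding accuracy per window (mean over
    ``n_repeats`` repetitions of stratified ``n_folds``-fold CV)."""
    rng = np.random.default_rng(seed)
    X = counts.counts
    y = counts.labels
    if balance:
        keep = balance_labels(y, rng)
        X, y = X[keep], y[keep]
    _, cnts = np.unique(y, return_counts=True)
    if cnts.min() < n_folds:
        raise ValueError("fewer trials per class than folds")
    n_win = X.shape[2]
    acc = np.zeros(n_win)
    splits = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        splits.extend(skf.split(np.zeros(len(y)), y))
    for wi in range(n_win):
        Xi = X[:, :, wi]
        acc[wi] = np.mean([_fit_predict_acc(Xi[tr], y[tr], Xi[te], y[te])
                           for tr, te in splits])
    peak = int(np.argmax(acc))  # earliest window on ties
    return DecodingResult(accuracy=acc, peak_accuracy=float(acc[peak]),
                          peak_window=peak, window_centers=counts.window_centers,
                          n_folds=n_folds, n_repeats=n_repeats)


def shuffle_null(counts: CountMatrix, n_shuffles: int = 100, seed: int = 0,
                 test_size: float = 0.2):
    """Null decoding accuracies from label permutations (one stratified 80/20
    split per shuffle). Returns (null array (n_shuffles, n_windows), 95th
    percentile per window)."""
    rng = np.random.default_rng(seed)
    X = counts.counts
    y = counts.labels.copy()
    n_win = X.shape[2]
    null = np.zeros((n_shuffles, n_win))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_size,
                                     random_state=int(rng.integers(2**31)))
        tr, te = next(sss.split(np.zeros(len(ys)), ys))
        for wi in range(n_win):
            null[s, wi] = _fit_predict_acc(X[tr][:, :, wi], ys[tr],
                                           X[te][:, :, wi], ys[te])
    if n_shuffles == 0:
        return null, None
    return null, np.percentile(null, 95, axis=0)


def model_feature_sample(ts: TrialSet, n_runs: int = 25, seed: int = 0,
                         window: float = 0.1, step: float = 0.02,
                         span=(-0.1, 0.6), n_folds: int = 5, n_repeats: int = 10
                         ) -> DecodingResult:
    """Decoding averaged over random cell subsamples: for a clustered network
    one E cell per cluster plus one background E cell (p+1 features); for a
    uniform network a matched number of random E cells."""
    rng = np.random.default_rng(seed)
    p = int(ts.unit_cluster[ts.unit_pop == 0].max())
    counts_full = sliding_counts(ts, window=window, step=step, span=span)
    e_cells = np.flatnonzero(ts.unit_pop == 0)
    clustered = np.any(ts.unit_cluster[e_cells] < p)
    accs = []
    pos_of = {u: i for i, u in enumerate(counts_full.unit_ids)}
    for _ in range(max(n_runs, 1)):
        if clustered:
            feats = []
            for c in range(p + 1):
                mem = e_cells[ts.unit_cluster[e_cells] == c]
                if len(mem) == 0:
                    raise ValueError(f"cluster {c} has no recordable cells")
                feats.append(rng.choice(mem))
        else:
            feats = rng.choice(e_cells, size=p + 1, replace=False)
        idx = np.array([pos_of[u] for u in feats])
        sub = CountMatrix(counts=counts_full.counts[:, idx, :],
                          labels=counts_full.labels,
                          window_centers=counts_full.window_centers,
                          window=window, step=step, unit_ids=np.asarray(feats))
        res = decode_timecourse(sub, n_folds=n_folds, n_repeats=n_repeats,
                                seed=int(rng.integers(2**31)))
        accs.append(res.accuracy)
    acc = np.mean(accs, axis=0)
    peak = int(np.argmax(acc))
    return DecodingResult(accuracy=acc, peak_accuracy=float(acc[peak]),
                          peak_window=peak, window_centers=counts_full.window_centers,
                          n_folds=n_folds, n_repeats=n_repeats)


def dprime_pipeline(counts: CountMatrix, units: Optional[np.ndarray] = None
                    ) -> DiscriminabilityResult:
    """Pair-averaged single-cell d' per window, its cell-averaged timecourse,
    and the pair- and time-optimized summary Dsc'.

    Pairs with zero pooled variance in a window are dropped from that cell's
    pair average.
    """
    X = counts.counts.astype(float)
    y = counts.labels
    if units is not None:
        sel = np.isin(counts.unit_ids, units)
        X = X[:, sel, :]
    classes = np.unique(y)
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("need >= 2 trials per stimulus")
    mus = np.stack([X[y == c].mean(axis=0) for c in classes])   # (S, U, W)
    sds = np.stack([X[y == c].std(axis=0, ddof=1) for c in classes])
    n_u, n_w = X.shape[1], X.shape[2]
    dsum = np.zeros((n_u, n_w))
    dcnt = np.zeros((n_u, n_w))
    for a, b in combinations(range(len(classes)), 2):
        pooled = np.sqrt(0.5 * (sds[a] ** 2 + sds[b] ** 2))
        ok = pooled > 0
        d = np.zeros_like(pooled)
        d[ok] = np.abs(mus[a][ok] - mus[b][ok]) / pooled[ok]
        dsum += np.where(ok, d, 0.0)
        dcnt += ok
    with np.errstate(invalid="ignore"):
        d_cell_time = np.where(dcnt > 0, dsum / dcnt, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_time = np.nanmean(d_cell_time, axis=0)
    if not np.isfinite(d_time).any():
        return DiscriminabilityResult(
            dprime_cell_time=d_cell_time, dprime_time=d_time,
            Dsc_prime=float("nan"), t_star=0,
            dprime_cell_at_tstar=d_cell_time[:, 0],
            window_centers=counts.window_centers)
    t_star = int(np.nanargmax(d_time))
    return DiscriminabilityResult(
        dprime_cell_time=d_cell_time, dprime_time=d_time,
        Dsc_prime=float(d_time[t_star]), t_star=t_star,
        dprime_cell_at_tstar=d_cell_time[:, t_star],
        window_centers=counts.window_centers)


def central_vs_extreme_deciles(values_by_session: dict, which: str = "low",
                               low_cut: float = 25.0, high_cut: float = 75.0):
    """Compare a metric's central pupil decile to the first or last decile
    across sessions.

    ``values_by_session`` maps a session key to (decile_centers, values),
    both length-10 arrays ordered by pupil. The central decile is the one
    centered closest to 50% of maximum dilation. For ``which='low'`` only
    sessions whose first decile is centered below ``low_cut`` are included
    and the contrast is central - first; for ``which='high'`` sessions whose
    last decile is centered above ``high_cut``, contrast central - last.
    Returns (per-session differences, Wilcoxon signed-rank p-value or NaN if
    fewer than two sessions qualify).
    """
    from scipy import stats as _stats

    diffs = []
    for key, (centers, vals) in values_by_session.items():
        centers = np.asarray(centers, float)
        vals = np.asarray(vals, float)
        mid = int(np.argmin(np.abs(centers - 50.0)))
        if which == "low":
            if centers[0] >= low_cut:
                continue
            diffs.append(vals[mid] - vals[0])
        elif which == "high":
            if centers[-1] <= high_cut:
                continue
            diffs.append(vals[mid] - vals[-1])
        else:
            raise ValueError("which must be 'low' or 'high'")
    diffs = np.asarray(diffs)
    if len(diffs) < 2 or np.allclose(diffs, 0):
        return diffs, float("nan")
    return diffs, float(_stats.wilcoxon(diffs).pvalue)


def condition_normalize_and_bin(values_by_session: dict, bin_edges=None,
                                bin_width: float = 10.0, span=(0.0, 100.0)
                                ) -> pd.DataFrame:
    """Z-score values within each session/realization, bin them by their
    condition coordinate (pupil % or modulation strength), average duplicates
    within a session-bin, then aggregate across sessions.

    ``values_by_session`` maps a session key to a sequence of
    ``(condition, value)`` pairs. Sessions with fewer than two conditions (or
    zero variance) are excluded. Returns a tidy frame with one row per bin.
    """
    if bin_edges is None:
        bin_edges = np.arange(span[0], span[1] + 1e-9, bin_width)
    bin_edges = np.asarray(bin_edges, float)
    rows = []
    for sess, pairs in values_by_session.items():
        pairs = list(pairs)
        if len(pairs) < 2:
            continue
        cond = np.array([p[0] for p in pairs], float)
        val = np.array([p[1] for p in pairs], float)
        sd = val.std(ddof=0)
        if sd == 0:
            continue
        z = (val - val.mean()) / sd
        which = np.digitize(cond, bin_edges) - 1
        for b in np.unique(which):
            if 0 <= b < len(bin_edges) - 1:
                rows.append(dict(session=sess, bin=b,
                                 bin_center=0.5 * (bin_edges[b] + bin_edges[b + 1]),
                                 value=z[which == b].mean()))
    per_sess = pd.DataFrame(rows)
    if per_sess.empty:
        return per_sess
    out = per_sess.groupby(["bin", "bin_center"])["value"].agg(["mean", "std", "count"])
    return out.reset_index()
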