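"""Spike-train auto-/cross-correlograms and the spindle-rhythmicity metric.

A correlogram histograms the lags ``t_target - t_ref`` over all spike pairs
within a maximum lag, optionally restricted to intervals (rest periods or
spindle-cycle windows; both spikes must fall inside).  Significance of
correlogram peaks uses the same shared-shift permutation null as the PETH
machinery.  Rhythmicity in the spindle band is summarised by the lag of the
autocorrelogram maximum after the first local minimum that follows lag 0: a
unit firing at spindle periodicity peaks at a lag in [1/14, 1/6] s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class Correlogram:
    lags: np.ndarray       # bin centers, seconds
    counts: np.ndarray     # pair counts per bin
    rate: np.ndarray       # counts / (n_ref * bin_s), spikes/s per ref spike
    bin_s: float
    n_ref: int
    is_auto: bool
    z: np.ndarray | None = None
    null_params: dict | None = None


@dataclass
class AutocorrPeak:
    peak_lag_s: float
    peak_value: float
    in_spindle_band: bool
    min_lag_s: float


def _restrict(times: np.ndarray, intervals: np.ndarray | None) -> np.ndarray:
    if intervals is None:
        return times
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if not len(iv):
        return times[:0]
    idx = np.searchsorted(iv[:, 0], times, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(times), dtype=bool)
    out[ok] = times[ok] < iv[idx[ok], 1]
    return times[out]


def correlogram(ref: np.ndarray, target: np.ndarray, bin_s: float = 0.01,
                max_lag_s: float = 0.5,
                restrict: np.ndarray | None = None,
                is_auto: bool = False) -> Correlogram:
    """Histogram of target-minus-reference spike-time lags.

    ``restrict`` is an optional (n, 2) array of half-open intervals; only
    pairs with both spikes inside count.  Auto mode excludes the i = j
    self-pairs (the trains must then be identical).
    """
    ref_r = _restrict(np.asarray(ref, dtype=float), restrict)
    tgt_r = _restrict(np.asarray(target, dtype=float), restrict)
    n_side = int(round(max_lag_s / bin_s))
    # bins centered on multiples of bin_s, so a lag of exactly k*bin_s falls
    # in the bin spanning ((k-1/2) bin_s, (k+1/2) bin_s]
    edges = bin_s * (np.arange(-n_side, n_side + 2) - 0.5)
    centers = bin_s * np.arange(-n_side, n_side + 1)
    counts = np.zeros(len(centers), dtype=float)
    if not len(ref_r) or not len(tgt_r):
        warnings.warn("empty restriction overlap: empty correlogram")
        return Correlogram(lags=centers, counts=counts, rate=counts.copy(),
                           bin_s=bin_s, n_ref=len(ref_r), is_auto=is_auto)
    lo = np.searchsorted(tgt_r, ref_r - max_lag_s)
    hi = np.searchsorted(tgt_r, ref_r + max_lag_s)
    diffs = []
    for i, (a, b, t) in enumerate(zip(lo, hi, ref_r)):
        d = tgt_r[a:b] - t
        if is_auto:
            d = np.delete(d, i - a) if a <= i < b else d
        diffs.append(d)
    alld = np.concatenate(diffs) if diffs else np.empty(0)
    counts, _ = np.histogram(alld, bins=edges)
    counts = counts.astype(float)
    rate = counts / (len(ref_r) * bin_s)
    return Correlogram(lags=centers, counts=counts, rate=rate, bin_s=bin_s,
                       n_ref=len(ref_r), is_auto=is_auto)


def correlogram_zscore(ref: np.ndarray, target: np.ndarray,
                       bin_s: float = 0.01, max_lag_s: float = 0.5,
                       restrict: np.ndarray | None = None,
                       is_auto: bool = False, n_perms: int = 100,
                       shift_range_s: tuple[float, float] = (1.5, 2.5),
                       seed: int = 0) -> Correlogram:
    """Correlogram with per-bin z against a shifted-target permutation null.

    Each permutation rigidly shifts the target train by one shared offset
    (magnitude uniform in ``shift_range_s``, random sign) and recomputes the
    correlogram under the same restriction.
    """
    cc = correlogram(ref, target, bin_s, max_lag_s, restrict, is_auto)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perms, len(cc.counts)))
    for k in range(n_perms):
        off = rng.uniform(*shift_range_s) * rng.choice([-1.0, 1.0])
        null[k] = correlogram(ref, np.asarray(target) + off, bin_s, max_lag_s,
                              restrict, is_auto=False).counts
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc.z = np.where(sd > 0, (cc.counts - mu) / sd, np.nan)
    cc.null_params = {"n_perms": n_perms, "shift_range_s": shift_range_s,
                      "seed": seed}
    return cc


def autocorr_peak_after_min(acc: Correlogram,
                            spindle_band_hz: tuple[float, float] = (6.0, 14.0)
                            ) -> AutocorrPeak:
    """Lag of the autocorrelogram maximum after the first post-zero minimum.

    The local minimum is the first positive-lag bin whose two neighbours are
    both at least as large (ties broken toward smaller lag, with at least one
    strictly larger neighbour); the peak is the global maximum at larger
    lags.  ``in_spindle_band`` is true iff the peak lag lies within the
    spindle period range [1/14, 1/6] s.  Raises if the correlogram is
    monotone with no minimum.
    """
    pos = acc.lags > 0
    lags = acc.lags[pos]
    c = acc.counts[pos]
    if len(c) < 3:
        raise ValueError("correlogram too short for peak-after-minimum")
    min_idx = None
    for i in range(1, len(c) - 1):
        if (c[i - 1] >= c[i] <= c[i + 1]) and (c[i - 1] > c[i] or c[i + 1] > c[i]):
            min_idx = i
            break
    if min_idx is None or min_idx + 1 >= len(c):
        raise ValueError("no post-zero local minimum: rhythmicity undefined")
    rest_c = c[min_idx + 1:]
    k = int(np.argmax(rest_c))
    peak_lag = float(lags[min_idx + 1 + k])
    lo, hi = 1.0 / spindle_band_hz[1], 1.0 / spindle_band_hz[0]
    return AutocorrPeak(peak_lag_s=peak_lag, peak_value=float(rest_c[k]),
                        in_spindle_band=bool(lo <= peak_lag <= hi),
                        min_lag_s=float(lags[min_idx]))


def subsample_spikes(times: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Seeded random subsample of ``n`` spikes (e.g. matching MUA spike counts
    to the sparsest unit), returned sorted."""
    times = np.asarray(times, dtype=float)
    if n >= len(times):
        return times.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(times, size=n, replace=False))
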