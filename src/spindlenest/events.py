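"""Detection of non-REM oscillatory events from band-filtered LFPs.

Three event detectors operate inside detected rest intervals:

* **K-complexes (KCs)** — the delta-filtered (1-4 Hz) mPFC LFP is rectified
  (positive values zeroed) and squared; local maxima of the squared trace
  exceeding ``mean + 4 sd`` (statistics over rest) mark the down-states.
* **Spindle troughs** — local minima of the spindle-filtered (6-14 Hz) mPFC
  voltage at or below ``mean - 3 sd`` of the filtered trace over rest.
  Individual cycles are then segmented by the flanking voltage peaks.
* **Sharp-wave ripples (SWRs)** — supra-threshold (``mean + 3 sd``) runs of
  the squared, 5 ms-smoothed ripple-filtered (100-275 Hz) CA1 trace lasting
  at least 20 ms; runs closer than 20 ms merge into one event.  The SWR
  timestamp is the sample with the largest absolute ripple-band value.

Threshold statistics are always computed on the same trace that is
thresholded (squared trace for KCs/SWRs, filtered voltage for spindle
troughs), restricted to rest intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .filters import BandSignal
from .state import StateIntervals


@dataclass
class EventSeries:
    """Detected events of one kind with timestamps and per-event amplitude."""

    kind: str  # "KC" | "spindle_trough" | "SWR"
    times: np.ndarray
    amplitudes: np.ndarray
    durations_s: np.ndarray | None = None  # SWRs only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be sorted")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SpindleCycle:
    """One spindle cycle: trough plus flanking voltage peaks."""

    trough_t: float
    start_t: float
    end_t: float
    p2t_amplitude: float
    ripple_power: float = np.nan          # filled by the coupling module
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start_t < self.trough_t < self.end_t):
            raise ValueError("cycle must satisfy start < trough < end")
        if not self.p2t_amplitude > 0:
            raise ValueError("peak-to-trough amplitude must be positive")

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def _rest_stats(trace: np.ndarray, rest: StateIntervals, fs: float,
                t0: float) -> tuple[float, float]:
    mask = rest.sample_mask(len(trace), fs, t0=t0, label="rest")
    if not mask.any():
        return np.nan, np.nan
    seg = trace[mask]
    return float(seg.mean()), float(seg.std())


def _local_maxima(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def _local_minima(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1


def detect_kcomplexes(delta_band: BandSignal, rest: StateIntervals,
                      n_sd: float = 4.0, refractory_s: float = 0.25,
                      t0: float = 0.0) -> EventSeries:
    """Detect K-complexes on the rectified, squared delta-band mPFC LFP.

    Positive values of the filtered trace are zeroed before squaring, so only
    negative (down-state) deflections can trigger.  A 250 ms refractory
    period between detected maxima prevents double-counting one down-state
    (candidates are resolved largest-first).
    """
    x = delta_band.samples
    trace = np.where(x > 0, 0.0, x) ** 2
    mu, sd = _rest_stats(trace, rest, delta_band.fs, t0)
    if not np.isfinite(mu):
        warnings.warn("no rest intervals: returning empty KC series")
        return EventSeries("KC", np.empty(0), np.empty(0))
    thr = mu + n_sd * sd
    cand = _local_maxima(trace)
    cand = cand[trace[cand] > thr]
    t_cand = t0 + cand / delta_band.fs
    inside = rest.contains(t_cand)
    cand, t_cand = cand[inside], t_cand[inside]

    # greedy refractory resolution, largest amplitude first
    keep: list[int] = []
    for i in np.argsort(trace[cand])[::-1]:
        if all(abs(t_cand[i] - t_cand[j]) >= refractory_s for j in keep):
            keep.append(i)
    keep_sorted = sorted(keep, key=lambda i: t_cand[i])
    return EventSeries("KC", times=t_cand[keep_sorted],
                       amplitudes=trace[cand[keep_sorted]])


def detect_spindle_troughs(spindle_band: BandSignal, rest: StateIntervals,
                           n_sd: float = 3.0, t0: float = 0.0) -> EventSeries:
    """Detect spindle troughs: local minima 3 sd below the mean filtered voltage.

    Successive troughs closer than one period of the band's upper edge
    (1/14 s) collapse to the deeper one.
    """
    x = spindle_band.samples
    mu, sd = _rest_stats(x, rest, spindle_band.fs, t0)
    if not np.isfinite(mu):
        warnings.warn("no rest intervals: returning empty spindle-trough series")
        return EventSeries("spindle_trough", np.empty(0), np.empty(0))
    thr = mu - n_sd * sd
    cand = _local_minima(x)
    cand = cand[x[cand] <= thr]
    t_cand = t0 + cand / spindle_band.fs
    cand = cand[rest.contains(t_cand)]

    min_gap = 1.0 / spindle_band.band[1]
    kept: list[int] = []
    for i in cand:
        if kept and (i - kept[-1]) / spindle_band.fs < min_gap:
            if x[i] < x[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    kept_arr = np.asarray(kept, dtype=int)
    return EventSeries("spindle_trough", times=t0 + kept_arr / spindle_band.fs,
                       amplitudes=x[kept_arr])


def segment_spindle_cycles(spindle_band: BandSignal, troughs: EventSeries,
                           max_flank_s: float | None = None,
                           t0: float = 0.0) -> list[SpindleCycle]:
    """Segment each trough into a cycle bounded by flanking voltage peaks.

    Troughs lacking a flanking local maximum within one period of the band's
    lower edge (1/6 s for the spindle band) are dropped.  The peak-to-trough
    amplitude is the larger flanking peak minus the trough value.
    """
    x = spindle_band.samples
    fs = spindle_band.fs
    if max_flank_s is None:
        max_flank_s = 1.0 / spindle_band.band[0]
    peaks = _local_maxima(x)
    cycles: list[SpindleCycle] = []
    for t_tr, amp in zip(troughs.times, troughs.amplitudes):
        i = int(round((t_tr - t0) * fs))
        k = np.searchsorted(peaks, i)
        if k == 0 or k == len(peaks):
            continue
        pre, post = peaks[k - 1], peaks[k]
        if (i - pre) / fs > max_flank_s or (post - i) / fs > max_flank_s:
            continue
        p2t = max(x[pre], x[post]) - x[i]
        cycles.append(SpindleCycle(
            trough_t=t_tr, start_t=t0 + pre / fs, end_t=t0 + post / fs,
            p2t_amplitude=float(p2t),
        ))
    return cycles


def detect_swrs(ripple_band: BandSignal, rest: StateIntervals,
                n_sd: float = 3.0, min_dur_s: float = 0.02,
                merge_gap_s: float = 0.02, smooth_s: float = 0.005,
                t0: float = 0.0) -> EventSeries:
    """Detect sharp-wave ripples on the squared, smoothed ripple-band CA1 LFP.

    A 5 ms moving average stabilises the >= 20 ms duration test against
    single-sample dropouts.  Supra-threshold runs separated by less than
    ``merge_gap_s`` count as a single ripple event.
    """
    x = ripple_band.samples
    fs = ripple_band.fs
    nsm = max(1, int(round(smooth_s * fs)))
    sq = sps.fftconvolve(x ** 2, np.full(nsm, 1.0 / nsm), mode="same")
    mu, sd = _rest_stats(sq, rest, fs, t0)
    if not np.isfinite(mu):
        warnings.warn("no rest intervals: returning empty SWR series")
        return EventSeries("SWR", np.empty(0), np.empty(0),
                           durations_s=np.empty(0))
    thr = mu + n_sd * sd
    above = sq > thr
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))

    # merge runs separated by < merge_gap_s
    runs: list[list[int]] = []
    gap = int(round(merge_gap_s * fs))
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] < gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])

    min_len = int(round(min_dur_s * fs))
    times, amps, durs = [], [], []
    for s, e in runs:
        if e - s < min_len:
            continue
        peak = s + int(np.argmax(np.abs(x[s:e])))
        t_peak = t0 + peak / fs
        if not rest.contains(np.array([t_peak]))[0]:
            continue
        times.append(t_peak)
        amps.append(abs(x[peak]))
        durs.append((e - s) / fs)
    order = np.argsort(times)
    return EventSeries("SWR", times=np.asarray(times)[order],
                       amplitudes=np.asarray(amps)[order],
                       durations_s=np.asarray(durs)[order])
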