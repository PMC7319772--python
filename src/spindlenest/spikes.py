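"""Burst detection, state-conditioned firing rates, and peri-event bursting.

Thalamic bursts are detected with the extracellular criterion: a group of
action potentials with inter-spike intervals under 5 ms, preceded by at least
70 ms with no spikes (the silence reflects the hyperpolarisation needed to
de-inactivate T-type calcium channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventSeries
from .session import SpikeTrain
from .state import StateIntervals


@dataclass
class BurstAnnotation:
    burst_onsets: np.ndarray
    spikes_in_burst: np.ndarray  # bool per spike
    pct_burst: float

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)


@dataclass
class StateRates:
    rate_wake: float
    rate_rest: float
    rate_method: str  # "total-count" | "inverse-mean-isi"
    zero_spikes: bool = False
    undefined: bool = False


@dataclass
class PeriEventBurstComparison:
    """Observed vs shift-control burst statistics around events."""

    observed_pct_burst: float
    observed_n_spikes: int
    control_pct_burst_mean: float
    control_pct_burst_sd: float
    control_n_spikes_mean: float
    n_shifts: int
    seed: int
    n_events_dropped: int = 0


def detect_bursts(train: SpikeTrain, max_isi_s: float = 0.005,
                  min_silence_s: float = 0.07) -> BurstAnnotation:
    """Flag maximal runs of ISIs < 5 ms preceded by >= 70 ms of silence.

    The first spike of a session is treated as preceded by infinite silence,
    so it may start a burst.  All spikes of a qualifying run are flagged.
    """
    t = train.times
    if len(t) < 2:
        return BurstAnnotation(np.empty(0), np.zeros(len(t), dtype=bool), 0.0)
    isi = np.diff(t)
    in_run = isi < max_isi_s
    flags = np.zeros(len(t), dtype=bool)
    onsets = []
    i = 0
    while i < len(t) - 1:
        if in_run[i]:
            j = i
            while j < len(isi) and in_run[j]:
                j += 1
            # run spans spikes i..j; check pre-burst silence
            silence = np.inf if i == 0 else isi[i - 1]
            if silence >= min_silence_s:
                flags[i:j + 1] = True
                onsets.append(t[i])
            i = j
        else:
            i += 1
    pct = 100.0 * flags.mean() if len(t) else 0.0
    return BurstAnnotation(np.asarray(onsets), flags, float(pct))


def state_firing_rates(train: SpikeTrain, states: StateIntervals,
                       method: str = "total-count") -> StateRates:
    """Per-state firing rate, spikes outside all intervals ignored.

    ``total-count``: spike count / total state duration.
    ``inverse-mean-isi``: reciprocal of the mean inter-spike interval of the
    spikes falling in that state.
    """
    if method not in ("total-count", "inverse-mean-isi"):
        raise ValueError(f"unknown rate method {method!r}")
    rates = {}
    undefined = False
    zero = train.n_spikes == 0
    for label in ("wake", "rest"):
        dur = states.duration(label)
        sel = train.times[states.contains(train.times, label)]
        if dur <= 0:
            rates[label] = np.nan
            undefined = True
        elif method == "total-count":
            rates[label] = len(sel) / dur
        else:
            if len(sel) < 2:
                rates[label] = 0.0
                zero = zero or len(sel) == 0
            else:
                rates[label] = 1.0 / np.mean(np.diff(sel))
    return StateRates(rate_wake=rates["wake"], rate_rest=rates["rest"],
                      rate_method=method, zero_spikes=zero, undefined=undefined)


def _pct_burst_in_windows(times: np.ndarray, flags: np.ndarray,
                          centers: np.ndarray, half_window_s: float
                          ) -> tuple[float, int]:
    lo = np.searchsorted(times, centers - half_window_s)
    hi = np.searchsorted(times, centers + half_window_s)
    mask = np.zeros(len(times), dtype=bool)
    for a, b in zip(lo, hi):
        mask[a:b] = True
    n = int(mask.sum())
    pct = 100.0 * flags[mask].mean() if n else 0.0
    return float(pct), n


def burst_fraction_near_events(train: SpikeTrain, bursts: BurstAnnotation,
                               events: EventSeries, half_window_s: float = 1.0,
                               control_shift_min_s: float = 2.0,
                               control_shift_span_s: float = 3.0,
                               n_shifts: int = 100, seed: int = 0,
                               extent: tuple[float, float] | None = None
                               ) -> PeriEventBurstComparison:
    """Percent of burst spikes within +/- ``half_window_s`` of events, vs a
    shifted-event control.

    Each control draw shifts every event time independently by a two-sided
    uniform offset with magnitude in
    ``[control_shift_min_s, control_shift_min_s + control_shift_span_s]``.
    """
    if len(events) == 0:
        raise ValueError("events must be non-empty")
    centers = events.times
    dropped = 0
    if extent is not None:
        lo, hi = extent
        ok = (centers - half_window_s >= lo) & (centers + half_window_s < hi)
        dropped = int((~ok).sum())
        centers = centers[ok]
    obs_pct, obs_n = _pct_burst_in_windows(train.times, bursts.spikes_in_burst,
                                           centers, half_window_s)
    rng = np.random.default_rng(seed)
    ctrl_pct = np.empty(n_shifts)
    ctrl_n = np.empty(n_shifts)
    for k in range(n_shifts):
        mag = rng.uniform(control_shift_min_s,
                          control_shift_min_s + control_shift_span_s,
                          size=len(centers))
        sign = rng.choice([-1.0, 1.0], size=len(centers))
        shifted = np.sort(centers + sign * mag)
        ctrl_pct[k], ctrl_n[k] = _pct_burst_in_windows(
            train.times, bursts.spikes_in_burst, shifted, half_window_s)
    return PeriEventBurstComparison(
        observed_pct_burst=obs_pct, observed_n_spikes=obs_n,
        control_pct_burst_mean=float(ctrl_pct.mean()),
        control_pct_burst_sd=float(ctrl_pct.std(ddof=1)),
        control_n_spikes_mean=float(ctrl_n.mean()),
        n_shifts=n_shifts, seed=seed, n_events_dropped=dropped,
    )
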