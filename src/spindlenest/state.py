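"""Rest-state (non-REM) detection and animal velocity.

Rest is defined by a conjunction of band powers: both the mPFC delta-band
(1-4 Hz) and CA1 ripple-band (100-275 Hz) power envelopes must exceed their
own session means contiguously for at least two minutes.  Velocity from the
30 Hz position track is computed and reported as a sanity check on detected
rest (the animal should be immobile), not used as a hard gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .session import PositionTrack


@dataclass
class StateIntervals:
    """Non-overlapping, sorted half-open [start, end) rest and wake intervals."""

    rest: np.ndarray  # (n, 2) seconds
    wake: np.ndarray  # (m, 2) seconds
    extent: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.rest = np.asarray(self.rest, dtype=float).reshape(-1, 2)
        self.wake = np.asarray(self.wake, dtype=float).reshape(-1, 2)
        for name, iv in (("rest", self.rest), ("wake", self.wake)):
            if len(iv) and np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError(f"{name} intervals must have end > start")
            if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError(f"{name} intervals must be sorted, non-overlapping")

    def intervals(self, label: str) -> np.ndarray:
        return self.rest if label == "rest" else self.wake

    def duration(self, label: str) -> float:
        iv = self.intervals(label)
        return float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0

    def contains(self, times: np.ndarray, label: str = "rest") -> np.ndarray:
        """Boolean mask: does each time fall inside an interval of ``label``?"""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        iv = self.intervals(label)
        if not len(iv):
            return np.zeros(len(times), dtype=bool)
        idx = np.searchsorted(iv[:, 0], times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(times), dtype=bool)
        out[ok] = times[ok] < iv[idx[ok], 1]
        return out

    def sample_mask(self, n: int, fs: float, t0: float = 0.0,
                    label: str = "rest") -> np.ndarray:
        """Per-sample boolean mask over an LFP grid of ``n`` samples."""
        mask = np.zeros(n, dtype=bool)
        for s, e in self.intervals(label):
            i0 = max(0, int(np.ceil((s - t0) * fs)))
            i1 = min(n, int(np.ceil((e - t0) * fs)))
            if i1 > i0:
                mask[i0:i1] = True
        return mask


@dataclass
class VelocityTrace:
    """Speed (cm/s) resampled to the LFP rate; ``valid`` is False inside
    position gaps longer than the interpolation limit."""

    t: np.ndarray
    v: np.ndarray
    valid: np.ndarray = field(repr=False)


def compute_velocity(track: PositionTrack, gap_max_s: float = 0.3,
                     smooth_sd_s: float = 0.25, fs_out: float = 600.0) -> VelocityTrace:
    """Speed from the position track.

    Gaps up to ``gap_max_s`` are linearly interpolated; longer gaps are masked
    invalid.  Speed is the Euclidean norm of the position derivative, smoothed
    with a Gaussian kernel (``smooth_sd_s`` standard deviation) and linearly
    interpolated to ``fs_out`` (the LFP rate).
    """
    good = ~track.missing
    if good.sum() < 2:
        warnings.warn("position track has fewer than 2 valid samples")
        return VelocityTrace(t=np.empty(0), v=np.empty(0),
                             valid=np.empty(0, dtype=bool))

    t, x, y = track.t, track.x.copy(), track.y.copy()
    x[~good] = np.interp(t[~good], t[good], x[good])
    y[~good] = np.interp(t[~good], t[good], y[good])

    # mark samples inside gaps longer than gap_max_s as invalid
    valid = np.ones(len(t), dtype=bool)
    gi = np.flatnonzero(good)
    prev_good = t[gi[np.clip(np.searchsorted(gi, np.arange(len(t)), "right") - 1, 0, None)]]
    next_good = t[gi[np.clip(np.searchsorted(gi, np.arange(len(t)), "left"), None, len(gi) - 1)]]
    gap = next_good - prev_good
    valid[~good & (gap > gap_max_s)] = False
    valid[: gi[0]] = t[: gi[0]] >= t[gi[0]]   # leading missing samples
    valid[gi[-1] + 1:] = False                 # trailing missing samples

    dt = np.gradient(t)
    speed = np.hypot(np.gradient(x), np.gradient(y)) / dt
    fs_in = 1.0 / np.median(dt)
    speed = gaussian_filter1d(speed, sigma=smooth_sd_s * fs_in, mode="nearest")

    t_out = np.arange(t[0], t[-1], 1.0 / fs_out)
    v_out = np.interp(t_out, t, speed)
    valid_out = np.interp(t_out, t, valid.astype(float)) >= 1.0 - 1e-9
    return VelocityTrace(t=t_out, v=np.maximum(v_out, 0.0), valid=valid_out)


def detect_rest_intervals(delta_env: np.ndarray, ripple_env: np.ndarray,
                          fs: float, min_duration_s: float = 120.0,
                          bridge_s: float = 10.0, t0: float = 0.0) -> StateIntervals:
    """Detect rest intervals where both power envelopes exceed their own means.

    Each envelope is compared to its session mean (making the rule invariant
    to affine rescaling of either envelope).  Brief sub-threshold dips up to
    ``bridge_s`` (default: the envelope-window scale) inside a candidate
    interval are bridged — a logged stand-in
    for the visual confirmation step a human scorer would perform.  Runs of
    joint supra-mean activity lasting at least ``min_duration_s`` become rest;
    the complement is wake.
    """
    delta_env = np.asarray(delta_env, dtype=float)
    ripple_env = np.asarray(ripple_env, dtype=float)
    if delta_env.shape != ripple_env.shape:
        raise ValueError("envelopes must have the same length")
    joint = (delta_env > delta_env.mean()) & (ripple_env > ripple_env.mean())

    edges = np.diff(joint.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if joint[0]:
        starts.insert(0, 0)
    if joint[-1]:
        ends.append(len(joint))

    # bridge brief dips
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) / fs <= bridge_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    rest = [(t0 + s / fs, t0 + e / fs) for s, e in merged
            if (e - s) / fs >= min_duration_s]
    extent = (t0, t0 + len(joint) / fs)
    wake = complement_intervals(np.array(rest).reshape(-1, 2), extent)
    return StateIntervals(rest=np.array(rest).reshape(-1, 2), wake=wake,
                          extent=extent)


def complement_intervals(intervals: np.ndarray,
                         extent: tuple[float, float]) -> np.ndarray:
    """Complement of sorted non-overlapping intervals within ``extent``."""
    lo, hi = extent
    out = []
    cur = lo
    for s, e in intervals:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if hi > cur:
        out.append((cur, hi))
    return np.array(out).reshape(-1, 2)
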