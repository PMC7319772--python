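"""Spike-LFP phase locking: phase estimation, circular statistics, pair lags.

Instantaneous phase of a band-filtered LFP is estimated either from the
analytic signal (Hilbert transform) or by piecewise-linear interpolation
between detected extrema.  Both use the cosine convention: phase 0 at the
band-signal peak, +/- pi at the trough, increasing with time.

Because non-sinusoidal LFP morphology biases phase sampling, spike-phase
distributions are normalised by the baseline distribution of phases over the
whole filtered trace during non-REM sleep.  Circular statistics on the
normalised distribution weight each spike phase by the inverse baseline
density (weights scaled to mean 1, so the effective n equals the spike
count).  Phase locking is then quantified by the Rayleigh test (Z = n R^2)
and a von Mises fit (mean direction mu, concentration kappa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .filters import BandSignal

KAPPA_CAP = 1e3  # concentration cap for near-degenerate samples


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap radians to (-pi, pi]."""
    out = -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)
    return out


@dataclass
class PhaseTrace:
    t: np.ndarray
    phi: np.ndarray          # (-pi, pi], 0 at band-signal peak
    unwrapped_phi: np.ndarray
    fs: float
    method: str              # "hilbert" | "extrema"


@dataclass
class PhaseStats:
    n: int
    bin_centers: np.ndarray
    hist: np.ndarray         # baseline-normalised probability, sums to 1
    rayleigh_Z: float
    rayleigh_p: float
    mu: float
    kappa: float
    kappa_capped: bool = False


@dataclass
class PairPhaseLags:
    lags: np.ndarray         # radians in (-2pi, 2pi)
    sd_lag: float
    n_discarded: int = 0


def _alternating_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of alternating peaks/troughs; duplicate same-type extrema keep
    the more extreme one."""
    peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
    troughs = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
    idx = np.concatenate([peaks, troughs])
    is_peak = np.concatenate([np.ones(len(peaks), bool),
                              np.zeros(len(troughs), bool)])
    order = np.argsort(idx)
    idx, is_peak = idx[order], is_peak[order]
    keep_idx: list[int] = []
    keep_type: list[bool] = []
    for i, p in zip(idx, is_peak):
        if keep_type and keep_type[-1] == p:
            better = x[i] > x[keep_idx[-1]] if p else x[i] < x[keep_idx[-1]]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_type.append(bool(p))
    return np.asarray(keep_idx), np.asarray(keep_type)


def estimate_phase(band: BandSignal, method: str = "hilbert",
                   t0: float = 0.0) -> PhaseTrace:
    """Instantaneous phase of a narrowband signal.

    ``hilbert``: angle of the analytic signal.  ``extrema``: piecewise-linear
    phase anchored at detected peaks (0 mod 2pi) and troughs (pi mod 2pi) —
    the anchor convention that makes the two methods agree on a sinusoid.
    """
    x = band.samples
    t = t0 + np.arange(len(x)) / band.fs
    if method == "hilbert":
        phi = np.angle(sps.hilbert(x))
        unwrapped = np.unwrap(phi)
    elif method == "extrema":
        idx, is_peak = _alternating_extrema(x)
        if len(idx) < 2:
            raise ValueError("extrema method needs at least 2 extrema")
        # cumulative phase: consecutive alternating extrema are pi apart
        anchor_phase = np.pi * np.arange(len(idx), dtype=float)
        if not is_peak[0]:
            anchor_phase += np.pi  # first anchor is a trough
        unwrapped = np.interp(np.arange(len(x)), idx, anchor_phase)
        # linear extrapolation beyond the first/last anchor
        slope0 = (anchor_phase[1] - anchor_phase[0]) / (idx[1] - idx[0])
        slope1 = (anchor_phase[-1] - anchor_phase[-2]) / (idx[-1] - idx[-2])
        head = np.arange(idx[0])
        tail = np.arange(idx[-1] + 1, len(x))
        unwrapped[head] = anchor_phase[0] - slope0 * (idx[0] - head)
        unwrapped[tail] = anchor_phase[-1] + slope1 * (tail - idx[-1])
        phi = wrap_phase(unwrapped)
    else:
        raise ValueError(f"unknown phase method {method!r}")
    return PhaseTrace(t=t, phi=phi, unwrapped_phi=unwrapped, fs=band.fs,
                      method=method)


def phases_at_times(phase: PhaseTrace, times: np.ndarray
                    ) -> tuple[np.ndarray, int]:
    """Circular-aware phase at arbitrary times (interpolated on the unwrapped
    phase).  Out-of-range times are dropped; returns (phases, n_dropped)."""
    times = np.asarray(times, dtype=float)
    ok = (times >= phase.t[0]) & (times <= phase.t[-1])
    unw = np.interp(times[ok], phase.t, phase.unwrapped_phi)
    return wrap_phase(unw), int((~ok).sum())


def normalized_phase_histogram(spike_phases: np.ndarray,
                               baseline_phases: np.ndarray,
                               n_bins: int = 36
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Spike-phase probabilities divided by baseline probabilities, renormalised.

    Raises if a baseline bin touched by spikes is empty (normalisation
    undefined there).
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    spk, _ = np.histogram(wrap_phase(np.asarray(spike_phases)), bins=edges)
    base, _ = np.histogram(wrap_phase(np.asarray(baseline_phases)), bins=edges)
    bad = (base == 0) & (spk > 0)
    if bad.any():
        raise ValueError(f"empty baseline bin(s) touched by spikes: "
                         f"{np.flatnonzero(bad).tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(base > 0, spk / np.maximum(base, 1), 0.0)
    total = ratio.sum()
    if total == 0:
        raise ValueError("no spikes in any bin")
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, ratio / total


def _resultant(phases: np.ndarray, weights: np.ndarray | None
               ) -> tuple[float, float, float]:
    """(R, mean direction, effective n) of a possibly weighted circular sample."""
    phases = np.asarray(phases, dtype=float)
    if weights is None:
        weights = np.ones_like(phases)
    w = np.asarray(weights, dtype=float)
    n_eff = w.sum()
    c = np.sum(w * np.cos(phases)) / n_eff
    s = np.sum(w * np.sin(phases)) / n_eff
    return float(np.hypot(c, s)), float(np.arctan2(s, c)), float(n_eff)


def rayleigh_test(phases: np.ndarray, weights: np.ndarray | None = None
                  ) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (Z, p).

    Z = n R^2 with the resultant length R; p uses the standard approximation
    ``exp(sqrt(1 + 4n + 4(n^2 - n Z)) - (1 + 2n))``, monotone decreasing in Z.
    Weighted input uses the effective n = sum of weights.
    """
    phases = np.asarray(phases, dtype=float)
    if len(phases) < 2:
        raise ValueError("need at least 2 phase observations")
    R, _, n = _resultant(phases, weights)
    Z = n * R ** 2
    p = np.exp(np.sqrt(max(1 + 4 * n + 4 * (n ** 2 - n * Z), 0.0)) - (1 + 2 * n))
    return float(Z), float(min(p, 1.0))


def _A_inv(R: float) -> tuple[float, bool]:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = R; cap near-degenerate samples."""
    if R <= 0:
        return 0.0, False
    A = lambda k: i1e(k) / i0e(k)
    if R >= A(KAPPA_CAP):
        return KAPPA_CAP, True
    return float(brentq(lambda k: A(k) - R, 1e-12, KAPPA_CAP)), False


def vonmises_fit(phases: np.ndarray, weights: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """Von Mises fit: (mu, kappa) with kappa = A^-1(R), capped at 1e3."""
    phases = np.asarray(phases, dtype=float)
    if len(phases) < 2:
        raise ValueError("need at least 2 phase observations")
    R, mu, _ = _resultant(phases, weights)
    kappa, capped = _A_inv(R)
    if capped:
        warnings.warn("resultant length ~1: kappa capped")
    return float(mu), float(kappa)


def phase_stats(spike_phases: np.ndarray, baseline_phases: np.ndarray,
                n_bins: int = 36) -> PhaseStats:
    """Baseline-normalised circular statistics for one unit (or event series).

    Each spike phase is weighted by the inverse baseline density of its bin,
    weights scaled to mean 1 so the effective n equals the spike count.
    """
    spike_phases = wrap_phase(np.asarray(spike_phases, dtype=float))
    centers, hist = normalized_phase_histogram(spike_phases, baseline_phases,
                                               n_bins)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    base, _ = np.histogram(wrap_phase(np.asarray(baseline_phases)), bins=edges)
    dens = base / base.sum()
    idx = np.clip(np.digitize(spike_phases, edges) - 1, 0, n_bins - 1)
    w = 1.0 / dens[idx]
    w *= len(w) / w.sum()
    Z, p = rayleigh_test(spike_phases, weights=w)
    mu, kappa = vonmises_fit(spike_phases, weights=w)
    return PhaseStats(n=len(spike_phases), bin_centers=centers, hist=hist,
                      rayleigh_Z=Z, rayleigh_p=p, mu=mu, kappa=kappa,
                      kappa_capped=kappa >= KAPPA_CAP)


def pair_phase_lags(times_a: np.ndarray, times_b: np.ndarray,
                    phase: PhaseTrace,
                    restrict: np.ndarray | None = None) -> PairPhaseLags:
    """Phase lag between the spikes of two units on a common oscillation.

    Each spike of unit a is paired with the nearest-in-time spike of unit b;
    the lag is the difference of unwrapped phases at the two spike times.
    Pairs with |lag| >= 2 pi (more than one cycle apart) are discarded and
    counted.  ``restrict`` is an optional (n, 2) array of intervals both
    spikes must fall in.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if restrict is not None and len(restrict):
        def _inside(t):
            iv = np.asarray(restrict).reshape(-1, 2)
            idx = np.searchsorted(iv[:, 0], t, side="right") - 1
            ok = idx >= 0
            out = np.zeros(len(t), dtype=bool)
            out[ok] = t[ok] < iv[idx[ok], 1]
            return out
        times_a = times_a[_inside(times_a)]
        times_b = times_b[_inside(times_b)]
    if not len(times_a) or not len(times_b):
        warnings.warn("no spikes in the analysis window")
        return PairPhaseLags(np.empty(0), np.nan, 0)

    j = np.searchsorted(times_b, times_a)
    j_lo = np.clip(j - 1, 0, len(times_b) - 1)
    j_hi = np.clip(j, 0, len(times_b) - 1)
    nearest = np.where(np.abs(times_b[j_hi] - times_a)
                       < np.abs(times_b[j_lo] - times_a), j_hi, j_lo)
    unw_a = np.interp(times_a, phase.t, phase.unwrapped_phi)
    unw_b = np.interp(times_b[nearest], phase.t, phase.unwrapped_phi)
    lags = unw_a - unw_b
    keep = np.abs(lags) < 2 * np.pi
    kept = lags[keep]
    if not len(kept):
        warnings.warn("no retained pairs within one cycle")
        return PairPhaseLags(np.empty(0), np.nan, int((~keep).sum()))
    return PairPhaseLags(lags=kept, sd_lag=float(np.std(kept)),
                         n_discarded=int((~keep).sum()))
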