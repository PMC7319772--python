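"""Band-pass FIR filtering and power envelopes for sleep LFP analysis.

All oscillatory-event detection works on three canonical bands of the 600 Hz
LFP: delta (1-4 Hz, slow oscillation / K-complexes), spindle (6-14 Hz) and
ripple (100-275 Hz).  Filters are linear-phase FIRs designed with a blackman
window, with tap count set by the rule ``order = 6 * fs / bandwidth`` (rounded
up to the nearest even integer so the impulse response is symmetric about an
integer sample).  Application is forward-backward, so the net phase shift is
zero and event timestamps are not displaced by the filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: Canonical band presets (low Hz, high Hz).
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "spindle": (6.0, 14.0),
    "ripple": (100.0, 275.0),
}


@dataclass(frozen=True)
class FilterSpec:
    """A designed band-pass FIR filter.

    ``order`` is the filter order (number of taps minus one), always even so
    the symmetric impulse response has an integer group delay of ``order/2``
    samples.
    """

    band_low: float
    band_high: float
    fs: float
    order: int
    coefficients: np.ndarray = field(repr=False)
    window: str = "blackman"


@dataclass
class BandSignal:
    """A band-filtered signal, same length as its source."""

    samples: np.ndarray
    fs: float
    band: tuple[float, float]
    source_region: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def fir_order(fs: float, low: float, high: float) -> int:
    """Tap-count rule: six times the sampling-rate/bandwidth ratio, ceiled to even."""
    order = math.ceil(6.0 * fs / (high - low))
    if order % 2:
        order += 1
    return order


def design_fir_bandpass(fs: float, low: float, high: float) -> FilterSpec:
    """Design the blackman-window band-pass FIR for one analysis band.

    Raises
    ------
    ValueError
        If the band does not satisfy ``0 < low < high < fs/2``.
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    order = fir_order(fs, low, high)
    coefficients = sps.firwin(
        order + 1, [low, high], pass_zero=False, window="blackman", fs=fs
    )
    return FilterSpec(band_low=low, band_high=high, fs=fs, order=order,
                      coefficients=coefficients)


def apply_zero_phase(x: np.ndarray, spec: FilterSpec,
                     source_region: str = "") -> BandSignal:
    """Filter ``x`` with zero net phase shift (forward-backward application).

    The signal is reflect-padded by one filter length before filtering and
    trimmed afterwards, so detection near the edges is not contaminated by
    the filter transient.

    Raises
    ------
    ValueError
        If the signal is shorter than three filter orders (edge effects
        would dominate the output).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"signal length {len(x)} too short for filter order {spec.order}; "
            f"need > {3 * spec.order} samples"
        )
    pad = spec.order + 1
    padded = np.concatenate([x[1:pad + 1][::-1], x, x[-pad - 1:-1][::-1]])
    fwd = sps.fftconvolve(padded, spec.coefficients, mode="same")
    bwd = sps.fftconvolve(fwd[::-1], spec.coefficients, mode="same")[::-1]
    y = bwd[pad:pad + len(x)]
    return BandSignal(samples=y, fs=spec.fs,
                      band=(spec.band_low, spec.band_high),
                      source_region=source_region)


def filter_band(x: np.ndarray, fs: float, band: str | tuple[float, float],
                source_region: str = "") -> BandSignal:
    """Convenience: design + apply for a named preset or explicit (low, high)."""
    low, high = BAND_PRESETS[band] if isinstance(band, str) else band
    spec = design_fir_bandpass(fs, low, high)
    return apply_zero_phase(x, spec, source_region=source_region)


def power_envelope(band: BandSignal, window_s: float) -> np.ndarray:
    """Centered moving average of the squared band-filtered signal.

    This is the power trace used for rest-state detection; ``window_s`` is the
    moving-average length in seconds (must cover at least two samples).
    """
    if window_s < 2.0 / band.fs:
        raise ValueError(f"window_s must be >= 2/fs = {2.0 / band.fs:.4g} s")
    n = int(round(window_s * band.fs))
    sq = band.samples ** 2
    kernel = np.full(n, 1.0 / n)
    # reflect-pad so the envelope stays length-preserving and centered
    pad = n // 2 + 1
    padded = np.concatenate([sq[1:pad + 1][::-1], sq, sq[-pad - 1:-1][::-1]])
    env = sps.fftconvolve(padded, kernel, mode="same")[pad:pad + len(sq)]
    return np.maximum(env, 0.0)
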