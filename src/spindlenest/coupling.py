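"""Within-spindle-cycle ripple power, cycle classification, and coupling labels.

Each spindle cycle's ripple power is the mean squared ripple-band amplitude
over the cycle window (a power density, so short and long cycles are
comparable).  Cycles are split into low/high classes by the session median
(or upper quartile) of a chosen feature (ripple power or peak-to-trough
amplitude).  A SWR is coupled to spindles iff its timestamp falls inside a
cycle's [start, end) window; per-cycle spike participation statistics are
reported per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import EventSeries, SpindleCycle
from .filters import BandSignal
from .session import SpikeTrain


@dataclass
class CycleClassification:
    feature: str             # "ripple_power" | "p2t_amplitude"
    scheme: str              # "median" | "upper_quartile"
    labels: list[str]        # per-cycle "low" | "high"
    threshold: float = np.nan


@dataclass
class CycleSpikeStats:
    pct_cycles_with_spikes: float
    mean_spikes_per_cycle: float
    n_cycles: int
    undefined: bool = False


@dataclass
class SwrCouplingLabels:
    coupled: np.ndarray          # bool per SWR
    uncoupled_subsample: np.ndarray  # SWR times, matched count, seeded
    seed: int
    subsample_short: bool = False


def cycle_ripple_power(cycles: list[SpindleCycle], ripple_band: BandSignal,
                       t0: float = 0.0) -> list[SpindleCycle]:
    """Fill each cycle's ripple_power with the mean squared ripple-band sample
    over [start_t, end_t); cycles outside the signal extent are dropped."""
    fs = ripple_band.fs
    n = len(ripple_band.samples)
    out: list[SpindleCycle] = []
    dropped = 0
    for c in cycles:
        i0 = int(np.ceil((c.start_t - t0) * fs))
        i1 = int(np.ceil((c.end_t - t0) * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            dropped += 1
            continue
        c.ripple_power = float(np.mean(ripple_band.samples[i0:i1] ** 2))
        out.append(c)
    if dropped:
        warnings.warn(f"{dropped} cycle(s) outside ripple signal extent dropped")
    return out


def classify_cycles(cycles: list[SpindleCycle], feature: str = "ripple_power",
                    scheme: str = "median") -> CycleClassification:
    """Label cycles low/high by the session median (or 75th percentile) of the
    feature; ties go to low.  Labels are also written into each cycle's
    class_labels under ``"<feature>_<scheme>"``."""
    if len(cycles) < 4:
        raise ValueError("need at least 4 cycles to classify")
    if feature == "ripple_power":
        vals = np.array([c.ripple_power for c in cycles])
    elif feature == "p2t_amplitude":
        vals = np.array([c.p2t_amplitude for c in cycles])
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if np.any(~np.isfinite(vals)):
        raise ValueError("feature not filled for all cycles")
    if np.ptp(vals) == 0:
        raise ValueError("constant feature: no split possible")
    q = 50.0 if scheme == "median" else 75.0
    if scheme not in ("median", "upper_quartile"):
        raise ValueError(f"unknown scheme {scheme!r}")
    thr = float(np.percentile(vals, q))
    labels = ["high" if v > thr else "low" for v in vals]
    name = f"{feature}_{scheme}"
    for c, lab in zip(cycles, labels):
        c.class_labels[name] = lab
    return CycleClassification(feature=feature, scheme=scheme, labels=labels,
                               threshold=thr)


def label_swr_spindle_coupling(swrs: EventSeries, cycles: list[SpindleCycle],
                               seed: int = 0) -> SwrCouplingLabels:
    """Coupled iff the SWR timestamp falls in any cycle's [start, end) window;
    also draws a seeded matched-size subsample of uncoupled SWR times."""
    if len(cycles):
        starts = np.array([c.start_t for c in cycles])
        ends = np.array([c.end_t for c in cycles])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, swrs.times, side="right") - 1
        ok = idx >= 0
        coupled = np.zeros(len(swrs.times), dtype=bool)
        coupled[ok] = swrs.times[ok] < ends[idx[ok]]
    else:
        coupled = np.zeros(len(swrs.times), dtype=bool)
    uncoupled_times = swrs.times[~coupled]
    n_coupled = int(coupled.sum())
    short = len(uncoupled_times) < n_coupled
    if short:
        warnings.warn("fewer uncoupled than coupled SWRs: using all uncoupled")
        sub = uncoupled_times.copy()
    else:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(uncoupled_times, size=n_coupled,
                                 replace=False))
    return SwrCouplingLabels(coupled=coupled, uncoupled_subsample=sub,
                             seed=seed, subsample_short=short)


def per_cycle_spike_stats(train: SpikeTrain,
                          classification: CycleClassification,
                          cycles: list[SpindleCycle]
                          ) -> dict[str, CycleSpikeStats]:
    """Per class label: percent of cycles containing >= 1 spike, and the mean
    spike count per cycle."""
    stats: dict[str, CycleSpikeStats] = {}
    for label in ("low", "high"):
        sel = [c for c, lab in zip(cycles, classification.labels)
               if lab == label]
        if not sel:
            warnings.warn(f"class {label!r} has zero cycles")
            stats[label] = CycleSpikeStats(np.nan, np.nan, 0, undefined=True)
            continue
        counts = np.array([
            np.searchsorted(train.times, c.end_t)
            - np.searchsorted(train.times, c.start_t) for c in sel
        ])
        stats[label] = CycleSpikeStats(
            pct_cycles_with_spikes=100.0 * float(np.mean(counts > 0)),
            mean_spikes_per_cycle=float(counts.mean()),
            n_cycles=len(sel),
        )
    return stats
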