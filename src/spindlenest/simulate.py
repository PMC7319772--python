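"""Synthetic non-REM sessions with ground truth for every detector/estimator.

The generator emulates the statistical structure the analyses assume:

* **mPFC** — 1/f background noise plus, during sleep bouts, an ongoing
  bounded-amplitude slow (delta-band) rhythm.  K-complexes are planted as
  negative half-waves at troughs of that rhythm (a KC is an extreme
  down-state of the ongoing slow oscillation); each KC is followed, with some
  probability, by a spindle packet of 3-8 cycles at 8.5-11.5 Hz (the
  flat-passband core of the 6-14 Hz analysis band).
* **CA1** — 1/f noise with a ripple-band noise floor (elevated during sleep,
  as ripple-band power is in non-REM), plus 150 Hz ripple bursts planted near
  spindle troughs (von Mises phase jitter) and at a low background rate.
* **thalamus** — noise only.
* **spikes** — inhomogeneous Poisson per unit: state-dependent base rate,
  down-state suppression during KCs, von Mises spindle-phase modulation gated
  by per-cycle Bernoulli participation (optionally with a refractory of
  suppressed cycles after a participated one), multiplicative SWR gain, and
  rebound bursts planted after down-states.

Event amplitudes are calibrated empirically against the *background*
(pre-planting) rest statistics of the same detection trace each detector
thresholds, expressed in multiples of its standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0 as bessel_i0

from .filters import design_fir_bandpass, apply_zero_phase, BAND_PRESETS, BandSignal
from .phase import PhaseTrace, wrap_phase
from .session import PositionTrack, Session, SpikeTrain


@dataclass(frozen=True)
class UnitSpec:
    """Generative parameters of one simulated unit."""

    unit_id: str
    region: str
    base_rate_wake: float
    base_rate_sleep: float
    phase_mu: float = 0.0
    phase_kappa: float = 0.0
    participation_p: float = 1.0
    participation_refractory: int = 0   # cycles suppressed after participating
    burst_prob_per_down_state: float = 0.0
    intra_burst_isi_s: float = 0.003
    spikes_per_burst: tuple[int, int] = (2, 5)
    swr_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.participation_p <= 1.0):
            raise ValueError("participation_p must be in [0, 1]")
        if self.phase_kappa < 0 or self.base_rate_wake < 0 or self.base_rate_sleep < 0:
            raise ValueError("rates and kappa must be non-negative")


def default_units() -> tuple[UnitSpec, ...]:
    """A small mixed population: thalamic units (sleep-reduced rate, bursty,
    spindle-locked, suppressed during SWRs), CA1 units (SWR-activated), and
    one mPFC unit."""
    return (
        UnitSpec("thal1", "thalamus", base_rate_wake=10.0, base_rate_sleep=7.5,
                 phase_mu=0.8, phase_kappa=1.0, participation_p=0.25,
                 participation_refractory=1, burst_prob_per_down_state=0.6,
                 swr_gain=0.4),
        UnitSpec("thal2", "thalamus", base_rate_wake=8.0, base_rate_sleep=6.0,
                 phase_mu=0.4, phase_kappa=1.2, participation_p=0.25,
                 participation_refractory=1, burst_prob_per_down_state=0.5,
                 swr_gain=0.5),
        UnitSpec("ca1_1", "ca1", base_rate_wake=1.5, base_rate_sleep=1.2,
                 phase_mu=-1.7, phase_kappa=0.8, participation_p=0.2,
                 swr_gain=6.0),
        UnitSpec("ca1_2", "ca1", base_rate_wake=1.0, base_rate_sleep=0.9,
                 phase_mu=-1.5, phase_kappa=0.6, participation_p=0.2,
                 swr_gain=5.0),
        UnitSpec("mpfc1", "mpfc", base_rate_wake=5.0, base_rate_sleep=4.0,
                 phase_mu=0.2, phase_kappa=0.6, participation_p=0.4),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic session."""

    duration_s: float = 600.0
    fs_lfp: float = 600.0
    sleep_bouts: tuple[tuple[float, float], ...] = ((80.0, 520.0),)
    event_margin_s: float = 15.0     # events kept away from bout edges
    # K-complexes
    kc_rate_hz: float = 0.15
    kc_amp_sd: float = 8.0           # squared-trace peak, background rest-sd units
    kc_halfwave_s: float = 0.25
    kc_min_gap_s: float = 2.5
    kc_max_gap_s: float = 8.0        # non-REM keeps a steady KC supply
    # spindles
    spindle_per_kc: float = 0.8
    spindle_cycles: tuple[int, int] = (3, 8)
    spindle_freq_hz: tuple[float, float] = (8.5, 11.5)
    spindle_amp_sd: float = 9.0      # filtered-voltage, background rest-sd units
    spindle_delay_s: tuple[float, float] = (0.2, 0.4)
    # ripples / SWRs
    ripple_prob_per_cycle: float = 0.5
    ripple_freq_hz: float = 150.0
    ripple_dur_s: float = 0.05
    ripple_amp_sd: float = 9.0       # ripple-band voltage, background rest-sd units
    ripple_phase_kappa: float = 2.0
    swr_background_rate_hz: float = 0.15
    swr_min_gap_s: float = 0.08
    # background
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    delta_rhythm_amp: float = 3.0    # multiples of noise_sd
    delta_rhythm_freq_hz: tuple[float, float] = (1.7, 2.6)
    sleep_ripple_noise_gain: float = 2.5
    ripple_noise_frac: float = 0.5   # ripple-band floor amplitude vs noise_sd
    # units
    units: tuple[UnitSpec, ...] = field(default_factory=default_units)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = 0.0, self.duration_s
        for s, e in self.sleep_bouts:
            if not (lo <= s < e <= hi):
                raise ValueError(f"sleep bout ({s}, {e}) outside session")
        if not (0.0 <= self.spindle_per_kc <= 1.0
                and 0.0 <= self.ripple_prob_per_cycle <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        longest = (self.spindle_delay_s[1]
                   + (self.spindle_cycles[1] + 0.5) / self.spindle_freq_hz[0])
        if longest > self.kc_min_gap_s:
            raise ValueError(
                f"spindle packets (up to {longest:.2f} s after a KC) can outlast "
                f"the minimum KC gap {self.kc_min_gap_s} s"
            )


@dataclass
class GroundTruth:
    kc_times: np.ndarray
    spindle_trough_times: np.ndarray
    cycle_intervals: np.ndarray          # (n, 2) flanking-peak windows
    cycle_freq_hz: np.ndarray            # per cycle
    swr_times: np.ndarray
    swr_in_cycle: np.ndarray             # bool per SWR: planted inside a cycle
    sleep_bouts: np.ndarray
    burst_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    unit_specs: dict[str, UnitSpec] = field(default_factory=dict)


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """Unit-variance noise with 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[1:] /= f[1:] ** (exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _sample_inhomogeneous_poisson(lam: np.ndarray, fs: float,
                                  rng: np.random.Generator) -> np.ndarray:
    """Exact inhomogeneous Poisson times from a rate sampled on a grid."""
    counts = rng.poisson(lam / fs)
    idx = np.repeat(np.arange(len(lam)), counts)
    return np.sort((idx + rng.uniform(size=len(idx))) / fs)


def _bout_mask(n: int, fs: float, bouts, ramp_s: float = 1.0) -> np.ndarray:
    """Soft 0/1 mask of sleep bouts with short cosine ramps at the edges."""
    mask = np.zeros(n)
    r = int(ramp_s * fs)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
    for s, e in bouts:
        i0, i1 = int(s * fs), min(int(e * fs), n)
        mask[i0:i1] = 1.0
        if i0 + r < i1:
            mask[i0:i0 + r] = ramp
        if i1 - r > i0:
            mask[i1 - r:i1] = ramp[::-1]
    return mask


def simulate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its complete ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    sleep_soft = _bout_mask(n, fs, config.sleep_bouts)
    sleep_hard = sleep_soft >= 1.0

    # --- background channels -------------------------------------------------
    mpfc = config.noise_sd * one_over_f_noise(n, config.noise_exponent, rng)
    thal = config.noise_sd * one_over_f_noise(n, config.noise_exponent, rng)
    ca1 = config.noise_sd * one_over_f_noise(n, config.noise_exponent, rng)

    # ongoing slow rhythm in sleep: drifting frequency, bounded amplitude
    f_lo, f_hi = config.delta_rhythm_freq_hz
    f_inst = 0.5 * (f_lo + f_hi) + 0.5 * (f_hi - f_lo) * np.sin(
        2 * np.pi * 0.013 * t + rng.uniform(0, 2 * np.pi))
    phase_rhythm = 2 * np.pi * np.cumsum(f_inst) / fs
    amp_mod = 1.0 + 0.05 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    rhythm = (config.delta_rhythm_amp * config.noise_sd
              * amp_mod * np.sin(phase_rhythm) * sleep_soft)
    mpfc += rhythm

    # ripple-band noise floor in CA1, elevated during sleep
    rip_spec = design_fir_bandpass(fs, *BAND_PRESETS["ripple"])
    floor = apply_zero_phase(rng.standard_normal(n), rip_spec).samples
    floor *= config.ripple_noise_frac * config.noise_sd / floor.std()
    ca1 += floor * (1.0 + (config.sleep_ripple_noise_gain - 1.0) * sleep_soft)

    # --- amplitude calibration against background rest statistics ------------
    delta_spec = design_fir_bandpass(fs, *BAND_PRESETS["delta"])
    spindle_spec = design_fir_bandpass(fs, *BAND_PRESETS["spindle"])
    d_bg = apply_zero_phase(mpfc, delta_spec).samples[sleep_hard]
    kc_trace_bg = np.where(d_bg > 0, 0.0, d_bg) ** 2
    sd_kc = kc_trace_bg.std()
    sp_bg = apply_zero_phase(mpfc, spindle_spec).samples[sleep_hard]
    sd_sp = sp_bg.std()
    r_bg = apply_zero_phase(ca1, rip_spec).samples[sleep_hard]
    sd_rip = r_bg.std()

    a_kc = np.sqrt(config.kc_amp_sd * sd_kc)
    a_sp = config.spindle_amp_sd * sd_sp
    a_rip = config.ripple_amp_sd * sd_rip

    # --- K-complex times: troughs of the ongoing rhythm ----------------------
    ph_mod = np.mod(phase_rhythm, 2 * np.pi)
    trough_idx = np.flatnonzero(np.diff((ph_mod > 1.5 * np.pi).astype(np.int8)) == 1) + 1
    trough_t = trough_idx / fs
    in_margin = np.zeros(len(trough_t), dtype=bool)
    for s, e in config.sleep_bouts:
        in_margin |= ((trough_t >= s + config.event_margin_s)
                      & (trough_t < e - config.event_margin_s))
    trough_t = trough_t[in_margin]
    mean_trough_rate = len(trough_t) / max(sum(e - s for s, e in config.sleep_bouts), 1e-9)
    p_take = min(1.0, config.kc_rate_hz / max(mean_trough_rate, 1e-9))
    kc_times: list[float] = []
    bouts_arr = np.asarray(config.sleep_bouts, dtype=float).reshape(-1, 2)
    bout_of = np.searchsorted(bouts_arr[:, 0], trough_t, side="right") - 1
    last_t, last_bout = -np.inf, -1
    for tt, bi in zip(trough_t, bout_of):
        if tt - last_t < config.kc_min_gap_s:
            continue
        forced = bi == last_bout and tt - last_t > config.kc_max_gap_s
        if forced or rng.uniform() < p_take:
            kc_times.append(float(tt))
            last_t, last_bout = tt, bi
    kc_times_arr = np.asarray(kc_times)

    # plant KC half-waves
    w = config.kc_halfwave_s
    for tc in kc_times_arr:
        i0, i1 = int((tc - w / 2) * fs), int((tc + w / 2) * fs)
        seg = np.arange(max(i0, 0), min(i1, n))
        mpfc[seg] += -a_kc * np.cos(np.pi * (seg / fs - tc) / w)

    # --- spindle packets after KCs -------------------------------------------
    troughs_all: list[float] = []
    cycles_all: list[tuple[float, float]] = []
    cycle_freqs: list[float] = []
    for tc in kc_times_arr:
        if rng.uniform() >= config.spindle_per_kc:
            continue
        delay = rng.uniform(*config.spindle_delay_s)
        fpk = rng.uniform(*config.spindle_freq_hz)
        ncyc = int(rng.integers(config.spindle_cycles[0],
                                config.spindle_cycles[1] + 1))
        amp = a_sp * rng.uniform(1.0, 1.4)
        t0p = tc + w / 2 + delay
        # waveform runs half a cycle past the last trough's flanking peak so
        # every planted trough has both flanking peaks and the packet starts
        # and ends at zero crossings
        t1p = t0p + (ncyc + 0.5) / fpk
        i0, i1 = int(t0p * fs), min(int(t1p * fs), n)
        seg = np.arange(i0, i1)
        mpfc[seg] += amp * np.sin(2 * np.pi * fpk * (seg / fs - t0p))
        for k in range(ncyc):
            troughs_all.append(t0p + (k + 0.75) / fpk)
            cycles_all.append((t0p + (k + 0.25) / fpk, t0p + (k + 1.25) / fpk))
            cycle_freqs.append(fpk)
    troughs_arr = np.asarray(troughs_all)
    cycles_arr = np.asarray(cycles_all).reshape(-1, 2)
    cycle_freqs_arr = np.asarray(cycle_freqs)

    # --- ripples: nested near spindle troughs + background -------------------
    swr_times: list[float] = []
    swr_nested: list[bool] = []
    for tt, fpk in zip(troughs_arr, cycle_freqs_arr):
        if rng.uniform() < config.ripple_prob_per_cycle:
            dphi = rng.vonmises(0.0, config.ripple_phase_kappa)
            swr_times.append(float(tt + dphi / (2 * np.pi * fpk)))
            swr_nested.append(True)
    n_bg = rng.poisson(config.swr_background_rate_hz
                       * sum(e - s for s, e in config.sleep_bouts))
    for _ in range(n_bg):
        s, e = config.sleep_bouts[int(rng.integers(len(config.sleep_bouts)))]
        swr_times.append(float(rng.uniform(s + config.event_margin_s,
                                           e - config.event_margin_s)))
        swr_nested.append(False)
    order = np.argsort(swr_times)
    swr_times_arr = np.asarray(swr_times)[order]
    swr_nested_arr = np.asarray(swr_nested)[order]
    keep = np.ones(len(swr_times_arr), dtype=bool)
    for i in range(1, len(swr_times_arr)):
        prev = np.flatnonzero(keep[:i])
        if len(prev) and swr_times_arr[i] - swr_times_arr[prev[-1]] < config.swr_min_gap_s:
            keep[i] = False
    swr_times_arr = swr_times_arr[keep]
    swr_nested_arr = swr_nested_arr[keep]

    sig_r = config.ripple_dur_s / 4.0
    for tc in swr_times_arr:
        i0 = int((tc - 3 * sig_r) * fs)
        i1 = min(int((tc + 3 * sig_r) * fs), n)
        seg = np.arange(max(i0, 0), i1)
        ts = seg / fs - tc
        ca1[seg] += (a_rip * np.exp(-ts ** 2 / (2 * sig_r ** 2))
                     * np.cos(2 * np.pi * config.ripple_freq_hz * ts))

    # --- spikes ---------------------------------------------------------------
    units: list[SpikeTrain] = []
    burst_onsets: dict[str, np.ndarray] = {}
    for spec in config.units:
        lam = (spec.base_rate_sleep * sleep_soft
               + spec.base_rate_wake * (1.0 - sleep_soft))
        # down-state suppression around each KC
        for tc in kc_times_arr:
            i0, i1 = int((tc - w / 2) * fs), min(int((tc + w / 2) * fs), n)
            lam[max(i0, 0):i1] *= 0.15
        # spindle-phase modulation, per-cycle participation
        if spec.phase_kappa > 0 and len(cycles_arr):
            norm = bessel_i0(spec.phase_kappa)
            last_part = -10
            for ci, ((c0, c1), tt, fpk) in enumerate(
                    zip(cycles_arr, troughs_arr, cycle_freqs_arr)):
                if ci - last_part <= spec.participation_refractory and last_part >= 0:
                    continue
                if rng.uniform() >= spec.participation_p:
                    continue
                last_part = ci
                i0, i1 = int(c0 * fs), min(int(c1 * fs), n)
                seg = np.arange(max(i0, 0), i1)
                phi = wrap_phase(2 * np.pi * fpk * (seg / fs - tt) + np.pi)
                lam[seg] *= np.exp(spec.phase_kappa
                                   * np.cos(phi - spec.phase_mu)) / norm
        # SWR gain
        if spec.swr_gain != 1.0:
            half = config.ripple_dur_s / 2.0
            for tc in swr_times_arr:
                i0, i1 = int((tc - half) * fs), min(int((tc + half) * fs), n)
                lam[max(i0, 0):i1] *= spec.swr_gain
        times = _sample_inhomogeneous_poisson(lam, fs, rng)
        # rebound bursts after down-states
        onsets: list[float] = []
        if spec.burst_prob_per_down_state > 0:
            for tc in kc_times_arr:
                if rng.uniform() >= spec.burst_prob_per_down_state:
                    continue
                onset = tc + w / 2 + rng.uniform(0.0, 0.05)
                nspk = int(rng.integers(spec.spikes_per_burst[0],
                                        spec.spikes_per_burst[1] + 1))
                burst = onset + spec.intra_burst_isi_s * np.arange(nspk)
                lo_cut, hi_cut = onset - 0.07, burst[-1] + 0.005
                times = times[(times < lo_cut) | (times > hi_cut)]
                times = np.sort(np.concatenate([times, burst]))
                onsets.append(onset)
        times = np.unique(times)
        times = times[(times >= 0) & (times < config.duration_s)]
        units.append(SpikeTrain(unit_id=spec.unit_id, region=spec.region,
                                times=times))
        burst_onsets[spec.unit_id] = np.asarray(onsets)

    # --- position -------------------------------------------------------------
    fs_pos = 30.0
    tp = np.arange(0.0, config.duration_s, 1.0 / fs_pos)
    sleeping = np.zeros(len(tp), dtype=bool)
    for s, e in config.sleep_bouts:
        sleeping |= (tp >= s) & (tp < e)
    step = rng.standard_normal((2, len(tp))) * (8.0 / fs_pos)
    step[:, sleeping] = rng.standard_normal((2, sleeping.sum())) * 0.02
    xy = 25.0 + np.cumsum(step, axis=1)
    xy = np.clip(xy, 0.0, 50.0)

    session = Session(
        session_id=f"synthetic-{config.seed}", fs_lfp=fs,
        lfp={"mpfc": mpfc, "thalamus": thal, "ca1": ca1},
        units=units,
        position=PositionTrack(t=tp, x=xy[0], y=xy[1]),
    )
    truth = GroundTruth(
        kc_times=kc_times_arr,
        spindle_trough_times=troughs_arr,
        cycle_intervals=cycles_arr,
        cycle_freq_hz=cycle_freqs_arr,
        swr_times=swr_times_arr,
        swr_in_cycle=swr_nested_arr,
        sleep_bouts=np.asarray(config.sleep_bouts, dtype=float).reshape(-1, 2),
        burst_onsets=burst_onsets,
        unit_specs={u.unit_id: u for u in config.units},
    )
    return session, truth


def simulate_phase_locked_spikes(phase: PhaseTrace, mu: float, kappa: float,
                                 mean_rate: float, participation_p: float = 1.0,
                                 seed: int = 0,
                                 participation_refractory: int = 0
                                 ) -> np.ndarray:
    """Inhomogeneous Poisson spikes locked to a phase trace.

    Intensity is ``mean_rate * exp(kappa cos(phi - mu)) / I0(kappa)`` (mean
    ``mean_rate`` over the trace before gating), gated per oscillation cycle
    by Bernoulli(``participation_p``); after a participated cycle the next
    ``participation_refractory`` cycles are suppressed.
    """
    if kappa < 0 or mean_rate < 0:
        raise ValueError("kappa and mean_rate must be non-negative")
    rng = np.random.default_rng(seed)
    lam = mean_rate * np.exp(kappa * np.cos(phase.phi - mu)) / bessel_i0(kappa)
    if participation_p < 1.0 or participation_refractory > 0:
        cyc = np.floor((phase.unwrapped_phi - np.pi) / (2 * np.pi)).astype(int)
        cyc -= cyc.min()
        gate = np.zeros(cyc.max() + 1)
        last = -10 ** 9
        for c in range(len(gate)):
            if c - last <= participation_refractory and last >= 0:
                continue
            if rng.uniform() < participation_p:
                gate[c] = 1.0
                last = c
        lam = lam * gate[cyc]
    times = _sample_inhomogeneous_poisson(lam, phase.fs, rng)
    return times + phase.t[0]


def simulate_bursty_train(base_rate: float, duration_s: float,
                          burst_rate_hz: float = 0.0,
                          intra_burst_isi_s: float = 0.003,
                          spikes_per_burst: tuple[int, int] = (2, 5),
                          min_silence_s: float = 0.07, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Tonic Poisson background plus planted bursts; returns (times, onsets).

    Background spikes within ``min_silence_s`` before a planted burst onset
    are removed so every planted burst satisfies the silence criterion.
    """
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0, duration_s,
                                rng.poisson(base_rate * duration_s)))
    onsets: list[float] = []
    n_bursts = rng.poisson(burst_rate_hz * duration_s)
    cand = np.sort(rng.uniform(1.0, duration_s - 1.0, n_bursts))
    for onset in cand:
        if onsets and onset - onsets[-1] < 1.0:
            continue
        nspk = int(rng.integers(spikes_per_burst[0], spikes_per_burst[1] + 1))
        burst = onset + intra_burst_isi_s * np.arange(nspk)
        times = times[(times < onset - min_silence_s) | (times > burst[-1] + 0.005)]
        times = np.sort(np.concatenate([times, burst]))
        onsets.append(float(onset))
    return np.unique(times), np.asarray(onsets)


@dataclass
class PacketField:
    """A packeted 10 Hz-class oscillation: per-cycle windows and troughs."""

    cycle_intervals: np.ndarray    # (n, 2)
    trough_times: np.ndarray
    freq_hz: float
    duration_s: float


def make_packet_field(duration_s: float, freq_hz: float = 10.0,
                      packet_rate_hz: float = 0.4,
                      cycles_per_packet: tuple[int, int] = (3, 8),
                      seed: int = 0) -> PacketField:
    """Random spindle-like packets (no LFP samples, just cycle geometry)."""
    rng = np.random.default_rng(seed)
    max_len = cycles_per_packet[1] / freq_hz
    starts = np.sort(rng.uniform(0.5, duration_s - max_len - 0.5,
                                 rng.poisson(packet_rate_hz * duration_s)))
    cycles, troughs = [], []
    prev_end = -np.inf
    for s in starts:
        if s < prev_end + 0.3:
            continue
        ncyc = int(rng.integers(cycles_per_packet[0], cycles_per_packet[1] + 1))
        for k in range(ncyc):
            cycles.append((s + (k + 0.25) / freq_hz, s + (k + 1.25) / freq_hz))
            troughs.append(s + (k + 0.75) / freq_hz)
        prev_end = s + ncyc / freq_hz
    return PacketField(cycle_intervals=np.asarray(cycles).reshape(-1, 2),
                       trough_times=np.asarray(troughs), freq_hz=freq_hz,
                       duration_s=duration_s)


def simulate_sparse_population(field: PacketField, n_units: int = 8,
                               participation_p: float = 0.25,
                               kappa: float = 4.0, mu_spread: float = 0.8,
                               spikes_per_participation: float = 1.3,
                               base_rate: float = 0.5,
                               participation_refractory: int = 1,
                               seed: int = 0) -> list[np.ndarray]:
    """Sparsely participating units locked to a common packeted field.

    Each unit has a preferred phase drawn within ``+/- mu_spread/2`` of the
    trough; in a participated cycle it fires ``1 + Poisson`` spikes at von
    Mises phases around its preference, plus a tonic Poisson background.
    """
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    for _ in range(n_units):
        mu_u = np.pi + rng.uniform(-mu_spread / 2, mu_spread / 2)
        times = list(rng.uniform(0, field.duration_s,
                                 rng.poisson(base_rate * field.duration_s)))
        last = -10 ** 9
        for ci, tt in enumerate(field.trough_times):
            if ci - last <= participation_refractory and last >= 0:
                continue
            if rng.uniform() >= participation_p:
                continue
            last = ci
            nspk = 1 + rng.poisson(spikes_per_participation - 1.0)
            phis = rng.vonmises(mu_u, kappa, size=nspk)
            times.extend(tt + wrap_phase(phis - np.pi) / (2 * np.pi * field.freq_hz))
        trains.append(np.unique(times))
    return trains


def simulate_participation_spikes(cycles, labels: list[str],
                                  p_by_label: dict[str, float],
                                  spikes_when_active: float = 1.0,
                                  seed: int = 0) -> np.ndarray:
    """Spikes placed in cycles with class-dependent participation probability.

    ``cycles`` is a list of SpindleCycle (or (start, end) pairs); in each
    participated cycle the unit fires ``1 + Poisson(spikes_when_active - 1)``
    spikes uniformly inside the window.
    """
    rng = np.random.default_rng(seed)
    times: list[float] = []
    for c, lab in zip(cycles, labels):
        s, e = (c.start_t, c.end_t) if hasattr(c, "start_t") else c
        if rng.uniform() < p_by_label[lab]:
            nspk = 1 + rng.poisson(max(spikes_when_active - 1.0, 0.0))
            times.extend(rng.uniform(s, e, nspk))
    return np.unique(times)


def match_event_times(true_times: np.ndarray, detected_times: np.ndarray,
                      tol_s: float) -> dict:
    """Greedy one-to-one matching of detected to planted event times.

    Candidate pairs within ``tol_s`` are matched smallest-error first;
    returns recall, precision and the matched absolute errors.
    """
    true_times = np.asarray(true_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    pairs = []
    for i, tt in enumerate(true_times):
        lo = np.searchsorted(detected_times, tt - tol_s)
        hi = np.searchsorted(detected_times, tt + tol_s)
        for j in range(lo, hi):
            pairs.append((abs(detected_times[j] - tt), i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    errors = []
    for err, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        errors.append(err)
    n_match = len(errors)
    recall = n_match / len(true_times) if len(true_times) else np.nan
    precision = n_match / len(detected_times) if len(detected_times) else np.nan
    return {"n_matched": n_match, "recall": recall, "precision": precision,
            "errors_s": np.asarray(errors),
            "median_error_s": float(np.median(errors)) if errors else np.nan}
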