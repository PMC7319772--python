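"""Event detectors on constructed traces with closed-form expectations."""

import numpy as np
import pytest

import spindlenest as sn
from conftest import make_rest

FS = 600.0


def _band(x, band):
    return sn.BandSignal(np.asarray(x, float), FS, band)


def _noise_delta(n, rng, amp=1.0):
    """A bounded-amplitude in-band background for threshold statistics."""
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))


class TestKComplexes:
    def test_injected_halfwave_detected_once(self):
        rng = np.random.default_rng(0)
        n = int(120 * FS)
        x = _noise_delta(n, rng)
        rest = make_rest((0, 120.0), [(0, 120.0)])
        # squared rectified background: find its rest sd, inject 8x half-wave
        sq = np.where(x > 0, 0, x) ** 2
        a = np.sqrt(8.0 * sq.std())
        tc = 60.0
        w = 0.25
        seg = np.arange(int((tc - w / 2) * FS), int((tc + w / 2) * FS))
        x[seg] += -a * np.cos(np.pi * (seg / FS - tc) / w)
        kcs = sn.detect_kcomplexes(_band(x, (1, 4)), rest)
        assert len(kcs) == 1
        assert abs(kcs.times[0] - tc) <= 0.025

    def test_positive_deflection_ignored(self):
        rng = np.random.default_rng(1)
        n = int(120 * FS)
        x = _noise_delta(n, rng)
        tc, w = 60.0, 0.25
        seg = np.arange(int((tc - w / 2) * FS), int((tc + w / 2) * FS))
        x[seg] += 50.0 * np.cos(np.pi * (seg / FS - tc) / w)  # positive bump
        rest = make_rest((0, 120.0), [(0, 120.0)])
        kcs = sn.detect_kcomplexes(_band(x, (1, 4)), rest)
        assert np.all(np.abs(kcs.times - tc) > 0.2)

    def test_flat_trace_no_events(self):
        rest = make_rest((0, 120.0), [(0, 120.0)])
        kcs = sn.detect_kcomplexes(_band(np.zeros(int(120 * FS)), (1, 4)), rest)
        assert len(kcs) == 0

    def test_no_rest_warns_empty(self):
        rest = make_rest((0, 120.0), np.empty((0, 2)))
        with pytest.warns(UserWarning):
            kcs = sn.detect_kcomplexes(
                _band(np.ones(int(120 * FS)), (1, 4)), rest)
        assert len(kcs) == 0


class TestSpindleTroughs:
    def _baseline(self, n, rng):
        t = np.arange(n) / FS
        return 0.25 * np.sin(2 * np.pi * 9.0 * t + rng.uniform(0, 2 * np.pi))

    def test_loud_sinusoid_gives_periodic_troughs(self):
        rng = np.random.default_rng(2)
        n = int(100 * FS)
        x = self._baseline(n, rng)
        t = np.arange(n) / FS
        sd = x.std()
        burst = (t >= 50.0) & (t < 51.0)
        x[burst] += 4 * 3 * sd * np.sin(2 * np.pi * 10 * (t[burst] - 50.0))
        rest = make_rest((0, 100.0), [(0, 100.0)])
        tr = sn.detect_spindle_troughs(_band(x, (6, 14)), rest)
        inside = tr.times[(tr.times >= 50) & (tr.times < 51)]
        assert len(inside) == 10
        np.testing.assert_allclose(np.diff(inside), 0.1, atol=0.01)

    def test_subthreshold_sinusoid_ignored(self):
        rng = np.random.default_rng(3)
        n = int(100 * FS)
        x = self._baseline(n, rng)
        rest = make_rest((0, 100.0), [(0, 100.0)])
        tr = sn.detect_spindle_troughs(_band(x, (6, 14)), rest)
        assert len(tr) == 0

    def test_close_minima_collapse_to_deeper(self):
        # two dips 40 ms apart, second deeper, on a quiet baseline
        rng = np.random.default_rng(4)
        n = int(100 * FS)
        x = self._baseline(n, rng)
        sd = x.std()
        for tc, depth in ((50.0, 5 * sd), (50.04, 7 * sd)):
            seg = np.arange(int((tc - 0.01) * FS), int((tc + 0.01) * FS) + 1)
            x[seg] -= depth * np.cos(np.pi * (seg / FS - tc) / 0.02) ** 2
        rest = make_rest((0, 100.0), [(0, 100.0)])
        tr = sn.detect_spindle_troughs(_band(x, (6, 14)), rest)
        near = tr.times[np.abs(tr.times - 50.02) < 0.05]
        assert len(near) == 1
        assert abs(near[0] - 50.04) < 0.01  # the deeper one


class TestSpindleCycles:
    def test_pure_sinusoid_cycles(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        band = _band(x, (6, 14))
        rest = make_rest((0, 10.0), [(0, 10.0)])
        tr = sn.detect_spindle_troughs(band, rest, n_sd=0.5)
        cycles = sn.segment_spindle_cycles(band, tr)
        assert len(cycles) > 50
        durs = np.array([c.duration_s for c in cycles])
        p2t = np.array([c.p2t_amplitude for c in cycles])
        np.testing.assert_allclose(durs, 0.1, atol=0.005)
        np.testing.assert_allclose(p2t, 2.0, atol=0.05)
        for c in cycles:
            assert c.start_t < c.trough_t < c.end_t

    def test_trough_without_preceding_peak_dropped(self):
        # signal starts mid-descent: first trough has no preceding local max
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t - np.pi / 2 - 0.3)
        band = _band(x, (6, 14))
        troughs = sn.EventSeries("spindle_trough",
                                 times=np.array([np.argmin(x[:60]) / FS]),
                                 amplitudes=np.array([-1.0]))
        cycles = sn.segment_spindle_cycles(band, troughs)
        assert len(cycles) == 0

    def test_asymmetric_wave_p2t(self):
        # pre-peak 1.0 at t=0.1, trough -1.0 at 0.15, post-peak 0.6 at 0.2
        fs = FS
        t = np.arange(int(0.3 * fs)) / fs
        x = np.zeros_like(t)

        def bump(tc, amp, w=0.04):
            seg = np.abs(t - tc) < w / 2
            x[seg] += amp * np.cos(np.pi * (t[seg] - tc) / w) ** 2

        bump(0.10, 1.0)
        bump(0.15, -1.0)
        bump(0.20, 0.6)
        band = _band(x, (6, 14))
        troughs = sn.EventSeries("spindle_trough", times=np.array([0.15]),
                                 amplitudes=np.array([-1.0]))
        cycles = sn.segment_spindle_cycles(band, troughs)
        assert len(cycles) == 1
        assert cycles[0].p2t_amplitude == pytest.approx(2.0, abs=1e-9)


class TestSwrs:
    def _bg(self, n, rng):
        t = np.arange(n) / FS
        return 0.1 * np.sin(2 * np.pi * 150 * t + rng.uniform(0, 2 * np.pi))

    def _inject(self, x, tc, amp, dur=0.05, f=150.0):
        sig = dur / 4
        seg = np.arange(int((tc - 3 * sig) * FS), int((tc + 3 * sig) * FS))
        ts = seg / FS - tc
        x[seg] += amp * np.exp(-ts ** 2 / (2 * sig ** 2)) * np.cos(2 * np.pi * f * ts)

    def test_single_burst_detected(self):
        rng = np.random.default_rng(5)
        n = int(100 * FS)
        x = self._bg(n, rng)
        self._inject(x, 50.0, 9 * x.std())
        rest = make_rest((0, 100.0), [(0, 100.0)])
        swrs = sn.detect_swrs(sn.filter_band(x, FS, "ripple"), rest)
        assert len(swrs) == 1
        assert abs(swrs.times[0] - 50.0) <= 0.01
        assert swrs.durations_s[0] >= 0.02

    def test_nearby_bursts_merge(self):
        rng = np.random.default_rng(6)
        n = int(100 * FS)
        x = self._bg(n, rng)
        amp = 9 * x.std()
        self._inject(x, 50.0, amp)
        self._inject(x, 50.055, amp)  # two supra-threshold runs, gap < 20 ms
        rest = make_rest((0, 100.0), [(0, 100.0)])
        swrs = sn.detect_swrs(sn.filter_band(x, FS, "ripple"), rest)
        near = swrs.times[np.abs(swrs.times - 50.03) < 0.15]
        assert len(near) == 1

    def test_too_short_burst_rejected(self):
        rng = np.random.default_rng(7)
        n = int(100 * FS)
        x = self._bg(n, rng)
        self._inject(x, 50.0, 9 * x.std(), dur=0.012)
        rest = make_rest((0, 100.0), [(0, 100.0)])
        swrs = sn.detect_swrs(sn.filter_band(x, FS, "ripple"), rest)
        assert len(swrs) == 0


def test_dc_offset_invariance(analysed):
    """Adding a constant to the raw LFP does not change detections."""
    shifted = sn.filter_band(analysed.session.lfp["mpfc"] + 137.0, FS, "delta")
    kcs2 = sn.detect_kcomplexes(shifted, analysed.rest)
    np.testing.assert_allclose(kcs2.times, analysed.kcs.times, atol=1e-9)


def test_detector_recovery_on_synthetic_session(analysed):
    """End-to-end sanity on the shared fixture (full margins in acceptance)."""
    for true, det, tol in [(analysed.truth.kc_times, analysed.kcs.times, 0.025),
                           (analysed.truth.spindle_trough_times,
                            analysed.troughs.times, 0.005),
                           (analysed.truth.swr_times, analysed.swrs.times, 0.010)]:
        m = sn.match_event_times(true, det, tol)
        assert m["recall"] >= 0.9 and m["precision"] >= 0.9
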