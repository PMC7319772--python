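"""Phase estimation, circular statistics, baseline normalisation, pair lags."""

import numpy as np
import pytest
from scipy import stats

import spindlenest as sn

FS = 600.0


def _band(x, band=(6, 14)):
    return sn.BandSignal(np.asarray(x, dtype=float), FS, band)


def _cosine(freq=10.0, dur=30.0, phase=0.0):
    t = np.arange(int(dur * FS)) / FS
    return t, np.cos(2 * np.pi * freq * t + phase)


def circ_diff(a, b):
    return sn.wrap_phase(np.asarray(a) - np.asarray(b))


class TestEstimatePhase:
    @pytest.mark.parametrize("method", ["hilbert", "extrema"])
    def test_cosine_peaks_at_zero_troughs_at_pi(self, method):
        t, x = _cosine()
        tr = sn.estimate_phase(_band(x), method=method)
        mid = slice(int(5 * FS), int(25 * FS))
        peaks = np.flatnonzero((x[mid] > 0.999))
        troughs = np.flatnonzero((x[mid] < -0.999))
        assert np.all(np.abs(sn.wrap_phase(tr.phi[mid][peaks])) < 0.1)
        assert np.all(np.abs(np.abs(tr.phi[mid][troughs]) - np.pi) < 0.1)

    def test_sine_at_origin_is_minus_half_pi(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        tr = sn.estimate_phase(_band(x), method="hilbert")
        assert tr.phi[0] == pytest.approx(-np.pi / 2, abs=0.05)

    def test_methods_agree_on_sinusoid(self):
        t, x = _cosine()
        h = sn.estimate_phase(_band(x), method="hilbert")
        e = sn.estimate_phase(_band(x), method="extrema")
        mid = slice(int(5 * FS), int(25 * FS))
        assert np.max(np.abs(circ_diff(h.phi[mid], e.phi[mid]))) < 0.05

    def test_extrema_needs_two_extrema(self):
        with pytest.raises(ValueError):
            sn.estimate_phase(_band(np.linspace(0, 1, 1000)), method="extrema")


class TestPhasesAtTimes:
    def test_exact_sample(self):
        t, x = _cosine()
        tr = sn.estimate_phase(_band(x))
        phis, dropped = sn.phases_at_times(tr, np.array([tr.t[1234]]))
        assert dropped == 0
        assert phis[0] == pytest.approx(tr.phi[1234], abs=1e-9)

    def test_midpoint_interpolation(self):
        tr = sn.PhaseTrace(t=np.array([0.0, 1.0]),
                           phi=np.array([0.1, 0.2]),
                           unwrapped_phi=np.array([0.1, 0.2]),
                           fs=1.0, method="hilbert")
        phis, _ = sn.phases_at_times(tr, np.array([0.5]))
        assert phis[0] == pytest.approx(0.15)

    def test_interpolation_across_wrap(self):
        unw = np.array([3.1, 2 * np.pi - 3.1])  # wraps: 3.1 -> -3.1
        tr = sn.PhaseTrace(t=np.array([0.0, 1.0]),
                           phi=sn.wrap_phase(unw), unwrapped_phi=unw,
                           fs=1.0, method="hilbert")
        phis, _ = sn.phases_at_times(tr, np.array([0.5]))
        assert abs(abs(phis[0]) - np.pi) < 0.05  # near +/- pi, never ~0

    def test_out_of_range_dropped(self):
        t, x = _cosine(dur=5.0)
        tr = sn.estimate_phase(_band(x))
        _, dropped = sn.phases_at_times(tr, np.array([-1.0, 2.0, 99.0]))
        assert dropped == 2


class TestNormalizedHistogram:
    def test_uniform_baseline_is_identity(self):
        rng = np.random.default_rng(0)
        spikes = rng.uniform(-np.pi, np.pi, 5000)
        baseline = np.linspace(-np.pi + 1e-6, np.pi - 1e-6, 360000)
        centers, h = sn.normalized_phase_histogram(spikes, baseline)
        raw, _ = np.histogram(spikes, bins=np.linspace(-np.pi, np.pi, 37))
        np.testing.assert_allclose(h, raw / raw.sum(), atol=1e-3)

    def test_spikes_from_skewed_baseline_flatten(self):
        """Spikes drawn FROM the baseline distribution normalise flat
        (chi-square test against uniform as oracle)."""
        rng = np.random.default_rng(1)
        n = 20000
        baseline = rng.vonmises(0.7, 1.5, size=400000)
        spikes = rng.vonmises(0.7, 1.5, size=n)
        _, h = sn.normalized_phase_histogram(spikes, baseline)
        # per-bin sampling sd of the normalised probability is inflated by the
        # inverse baseline density: sd_i ~ (1/36) / sqrt(n p_i)
        p_i, _ = np.histogram(baseline, bins=np.linspace(-np.pi, np.pi, 37))
        p_i = p_i / p_i.sum()
        sd_i = (1 / 36) / np.sqrt(n * p_i)
        assert np.all(np.abs(h - 1 / 36) < 5 * sd_i + 1e-4)

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        _, h = sn.normalized_phase_histogram(rng.vonmises(0, 2, 500),
                                             rng.uniform(-np.pi, np.pi, 5000))
        assert h.sum() == pytest.approx(1.0)

    def test_empty_baseline_bin_raises(self):
        spikes = np.array([0.0, 0.01, 3.0])
        baseline = np.zeros(100)  # all baseline mass in the bin containing 0
        with pytest.raises(ValueError):
            sn.normalized_phase_histogram(spikes, baseline)


class TestRayleigh:
    def test_identical_phases(self):
        Z, p = sn.rayleigh_test(np.full(100, 1.3))
        assert Z == pytest.approx(100.0)
        assert p < 1e-10

    def test_symmetric_four_points(self):
        Z, p = sn.rayleigh_test(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert Z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_vonmises_sample_matches_bessel_ratio(self):
        rng = np.random.default_rng(3)
        phases = rng.vonmises(0.0, 1.0, size=2000)
        Z, p = sn.rayleigh_test(phases)
        # E[R] = I1(1)/I0(1) ~ 0.4464 -> Z ~ n R^2 ~ 398
        assert Z == pytest.approx(2000 * 0.4464 ** 2, rel=0.15)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        for kappa in (0.0, 0.5, 2.0):
            phases = rng.vonmises(1.0, kappa, size=300)
            Z, p = sn.rayleigh_test(phases)
            z_ref, p_ref = pingouin.circ_rayleigh(phases)
            assert Z == pytest.approx(z_ref, rel=1e-6)
            assert p == pytest.approx(p_ref, rel=1e-3, abs=1e-12)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            sn.rayleigh_test(np.array([0.5]))


class TestVonMisesFit:
    def test_uniform_sample_kappa_near_zero(self):
        rng = np.random.default_rng(5)
        mu, kappa = sn.vonmises_fit(rng.uniform(-np.pi, np.pi, 10000))
        assert kappa < 0.05

    def test_degenerate_sample_capped(self):
        with pytest.warns(UserWarning):
            mu, kappa = sn.vonmises_fit(np.full(50, np.pi / 4))
        assert mu == pytest.approx(np.pi / 4)
        assert kappa == sn.phase.KAPPA_CAP

    def test_parameter_recovery_kappa_one(self):
        rng = np.random.default_rng(6)
        phases = rng.vonmises(0.8, 1.0, size=2000)
        mu, kappa = sn.vonmises_fit(phases)
        assert abs(sn.wrap_phase(mu - 0.8)) < 0.1
        assert abs(kappa - 1.0) < 0.15

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        phases = rng.vonmises(-1.2, 3.0, size=3000)
        mu, kappa = sn.vonmises_fit(phases)
        kappa_ref, mu_ref, _ = stats.vonmises.fit(phases, fscale=1)
        assert abs(sn.wrap_phase(mu - mu_ref)) < 0.02
        assert kappa == pytest.approx(kappa_ref, rel=0.05)


class TestPhaseStats:
    def test_weighted_stats_on_skewed_baseline(self):
        """With spikes drawn from the baseline itself, the normalised
        statistics show no phase locking despite the skew."""
        rng = np.random.default_rng(8)
        baseline = rng.vonmises(0.5, 1.0, size=200000)
        spikes = rng.vonmises(0.5, 1.0, size=3000)
        st_ = sn.phase_stats(spikes, baseline)
        assert st_.kappa < 0.15
        raw_Z, _ = sn.rayleigh_test(spikes)
        assert st_.rayleigh_Z < raw_Z / 5

    def test_true_locking_survives_normalisation(self):
        rng = np.random.default_rng(9)
        baseline = rng.uniform(-np.pi, np.pi, 200000)
        spikes = rng.vonmises(-2.0, 2.0, size=2000)
        st_ = sn.phase_stats(spikes, baseline)
        assert st_.rayleigh_p < 1e-6
        assert abs(sn.wrap_phase(st_.mu + 2.0)) < 0.1
        assert st_.kappa == pytest.approx(2.0, rel=0.2)


class TestPairPhaseLags:
    def _phase_trace(self, freq=10.0, dur=200.0):
        t, x = _cosine(freq=freq, dur=dur)
        return sn.estimate_phase(_band(x))

    def test_quarter_cycle_delay(self):
        rng = np.random.default_rng(10)
        tr = self._phase_trace()
        # inter-spike gaps > 2 cycles so each a-spike's nearest b is its twin
        a = 1.0 + np.cumsum(rng.uniform(0.3, 0.6, 300))
        b = np.sort(a + 0.025)  # quarter cycle of 10 Hz
        lags = sn.pair_phase_lags(a, b, tr)
        # a fires a quarter cycle of phase BEFORE b
        assert abs(np.mean(lags.lags) + np.pi / 2) < 0.1

    def test_identical_trains_zero_lag(self):
        tr = self._phase_trace()
        a = np.arange(1.0, 190.0, 0.5)
        lags = sn.pair_phase_lags(a, a.copy(), tr)
        assert np.allclose(lags.lags, 0.0)
        assert lags.sd_lag == 0.0

    def test_independent_trains_more_dispersed(self):
        rng = np.random.default_rng(11)
        tr = self._phase_trace()
        a = np.sort(rng.uniform(1, 199, 400))
        locked = sn.pair_phase_lags(a, np.sort(a + 0.025), tr)
        indep = sn.pair_phase_lags(a, np.sort(rng.uniform(1, 199, 400)), tr)
        assert indep.sd_lag > locked.sd_lag

    def test_lags_within_two_cycles(self):
        rng = np.random.default_rng(12)
        tr = self._phase_trace()
        a = np.sort(rng.uniform(1, 199, 200))
        b = np.sort(rng.uniform(1, 199, 200))
        lags = sn.pair_phase_lags(a, b, tr)
        assert np.all(np.abs(lags.lags) < 2 * np.pi)
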