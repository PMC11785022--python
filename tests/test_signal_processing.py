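import numpy as np
import pytest

from nvc import signal_processing as sp
from nvc.errors import ParameterError


class TestBandPowerEnvelope:
    def test_dc_input_rejected_by_band(self):
        x = np.ones(30000)
        env = sp.band_power_envelope(x, 1000.0, sp.BANDS["gamma"])
        assert np.max(env.values) < 1e-6

    def test_sinusoid_mean_square(self):
        # 50 Hz sinusoid amplitude a -> steady-state envelope a^2 / 2
        t = np.arange(0, 60, 1e-3)
        a = 2.0
        env = sp.band_power_envelope(a * np.sin(2 * np.pi * 50 * t), 1000.0, (30.0, 100.0))
        steady = env.values[10 * 30 : -10 * 30]
        assert np.mean(steady) == pytest.approx(a**2 / 2, rel=0.05)

    def test_white_noise_band_fraction(self, rng):
        # Parseval on a flat spectrum: the envelope mean equals the fraction
        # of total variance passed by the (forward-backward) bandpass, i.e.
        # integral of |H|^4 over frequency / Nyquist; close to the ideal
        # bandwidth fraction 70/500.
        from scipy.signal import sosfreqz

        fs = 1000.0
        x = rng.standard_normal(300000)
        env = sp.band_power_envelope(x, fs, (30.0, 100.0))
        f, h = sosfreqz(sp.butter_sos(fs, (30.0, 100.0), "bandpass", 3), worN=8192, fs=fs)
        expected = np.trapezoid(np.abs(h) ** 4, f) / (fs / 2)
        assert np.mean(env.values) == pytest.approx(expected, rel=0.05)
        assert np.mean(env.values) == pytest.approx((100.0 - 30.0) / (fs / 2), rel=0.15)

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ParameterError):
            sp.band_power_envelope(np.zeros(1000), 100.0, (30.0, 100.0))

    def test_output_rate_and_nonnegativity(self, rng):
        env = sp.band_power_envelope(rng.standard_normal(10000), 1000.0, (30.0, 100.0))
        assert env.fs == 30.0
        assert env.values.size == 300
        assert (env.values >= 0).all()


class TestEmgEnvelope:
    def test_scaling_shifts_log_by_two(self, rng):
        fs = 10000.0
        x = rng.standard_normal(int(fs * 20))
        e1 = sp.emg_envelope(x, fs).values
        e2 = sp.emg_envelope(10 * x, fs).values
        # discard resampler edges
        np.testing.assert_allclose(e2[30:-30] - e1[30:-30], 2.0, atol=1e-6)

    def test_zero_signal_hits_floor(self):
        e = sp.emg_envelope(np.zeros(100000), 10000.0).values
        assert np.allclose(e, np.log10(sp.EMG_LOG_FLOOR), atol=1e-9)

    def test_low_fs_truncates_band_with_warning(self, rng):
        with pytest.warns(UserWarning, match="truncated"):
            e = sp.emg_envelope(rng.standard_normal(30000), 1000.0)
        assert e.band[1] < 500.0


class TestMultitaperSpectrum:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(30000)
        est = sp.multitaper_spectrum(x, 1000.0, nw=3.0, k=5)
        df = est.freqs[1] - est.freqs[0]
        assert est.values.sum() * df == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_peak_location(self):
        t = np.arange(0, 30, 1e-2)
        est = sp.multitaper_spectrum(np.sin(2 * np.pi * 10 * t), 100.0, nw=3.0, k=5)
        nw, _ = est.taper_params
        resolution = 2 * nw / 30.0
        assert abs(est.freqs[np.argmax(est.values)] - 10.0) <= resolution

    def test_halving_length_doubles_estimator_variance(self, rng):
        # chi^2 scaling: variance of the PSD estimate at fixed K is set by K,
        # but the band-averaged estimate variance scales with 1/n_freq_bins
        fs = 200.0
        long_vals, short_vals = [], []
        for _ in range(40):
            x = rng.standard_normal(4000)
            e_long = sp.multitaper_spectrum(x, fs, nw=3.0, k=5)
            e_short = sp.multitaper_spectrum(x[:2000], fs, nw=3.0, k=5)
            sel_l = (e_long.freqs > 20) & (e_long.freqs < 40)
            sel_s = (e_short.freqs > 20) & (e_short.freqs < 40)
            long_vals.append(e_long.values[sel_l].mean())
            short_vals.append(e_short.values[sel_s].mean())
        ratio = np.var(short_vals) / np.var(long_vals)
        assert 1.3 < ratio < 3.2

    def test_taper_count_validated(self):
        with pytest.raises(ParameterError):
            sp.multitaper_spectrum(np.zeros(1000), 100.0, nw=3.0, k=8)


class TestCoherence:
    def test_identical_signals_unity(self, rng):
        x = rng.standard_normal(3000)
        est = sp.coherence(x, x, 100.0, nw=3.0, k=5)
        assert np.allclose(est.values, 1.0, atol=1e-8)

    def test_independent_noise_below_bias_bound(self, rng):
        x = rng.standard_normal(30000)
        y = rng.standard_normal(30000)
        events = [(i * 1000, (i + 1) * 1000) for i in range(30)]
        est = sp.coherence(x, y, 100.0, nw=3.0, k=5, events=events)
        assert np.mean(est.values) < 3.0 / np.sqrt(5 * 30)

    def test_common_signal_fraction(self, rng):
        # x = s + n1, y = s + n2 with shared variance fraction rho2
        rho2 = 0.6
        n = 60000
        s = rng.standard_normal(n) * np.sqrt(rho2)
        x = s + rng.standard_normal(n) * np.sqrt(1 - rho2)
        y = s + rng.standard_normal(n) * np.sqrt(1 - rho2)
        events = [(i * 3000, (i + 1) * 3000) for i in range(20)]
        est = sp.coherence(x, y, 100.0, nw=3.0, k=5, events=events)
        sel = (est.freqs > 1) & (est.freqs < 40)
        assert np.mean(est.values[sel]) == pytest.approx(rho2, rel=0.10)

    def test_values_in_unit_interval(self, rng):
        est = sp.coherence(rng.standard_normal(2000), rng.standard_normal(2000), 100.0)
        assert (est.values >= 0).all() and (est.values <= 1).all()

    def test_length_mismatch_raises(self):
        with pytest.raises(ParameterError):
            sp.coherence(np.zeros(100), np.zeros(101), 10.0)


class TestCrossCorrelation:
    def test_autocorrelation_peak_one_at_zero(self, rng):
        x = rng.standard_normal(6000)
        lags, r = sp.cross_correlation(x, x, 100.0, max_lag_s=5.0)
        assert r[np.argmin(np.abs(lags))] == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(r) == np.argmin(np.abs(lags))

    def test_delayed_copy_peaks_at_positive_lag(self, rng):
        # y follows x by exactly 1 s -> peak at +1 s
        fs = 100.0
        x = rng.standard_normal(8000)
        xf = sp.lowpass(x, fs, 1.0)
        shift = int(fs)
        y = np.roll(xf, shift)
        lags, r = sp.cross_correlation(xf[shift:-shift], y[shift:-shift], fs, max_lag_s=5.0, prefilter=False)
        assert lags[np.argmax(r)] == pytest.approx(1.0, abs=0.05)

    def test_independent_noise_null_bound(self, rng):
        n = 10000
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        lags, r = sp.cross_correlation(x, y, 100.0, max_lag_s=5.0, prefilter=False)
        assert np.max(np.abs(r)) < 4.0 / np.sqrt(n)

    def test_max_lag_validated(self):
        with pytest.raises(ParameterError):
            sp.cross_correlation(np.zeros(50), np.zeros(50), 100.0, max_lag_s=5.0)

    def test_zero_phase_filters_keep_pulse_symmetric(self):
        fs = 100.0
        x = np.zeros(2001)
        x[900:1101] = np.hanning(201)
        y = sp.lowpass(x, fs, 1.0)
        assert np.argmax(y) == 1000
        np.testing.assert_allclose(y, y[::-1], atol=1e-9)


class TestHeartRateEstimate:
    def test_constructed_pulsation(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = 1000 + 5 * np.sin(2 * np.pi * 8.0 * t)
        rates = sp.heart_rate_estimate(x, fs)
        assert np.nanmean(rates) == pytest.approx(8.0, abs=0.2)

    def test_vasomotion_only_missing(self):
        fs = 30.0
        t = np.arange(0, 60, 1 / fs)
        x = 1000 + 50 * np.sin(2 * np.pi * 0.1 * t)
        rates = sp.heart_rate_estimate(x, fs)
        assert np.isnan(rates).all()

    def test_chirp_monotone(self):
        fs = 30.0
        t = np.arange(0, 100, 1 / fs)
        inst_f = 6.0 + 4.0 * t / 100.0
        phase = 2 * np.pi * np.cumsum(inst_f) / fs
        rates = sp.heart_rate_estimate(1000 + 5 * np.sin(phase), fs)
        valid = rates[~np.isnan(rates)]
        assert valid.size >= 15
        assert (np.diff(valid) >= -0.25).all()
        assert valid[-1] > valid[0] + 2.0

    def test_low_fs_rejected(self):
        with pytest.raises(ParameterError):
            sp.heart_rate_estimate(np.zeros(1000), 20.0)


def test_spectrogram_shapes_and_periodicity(rng):
    fs = 100.0
    seg = rng.standard_normal(1000)
    x = np.tile(seg, 4)
    est = sp.multitaper_spectrogram(x, fs, window_s=5.0, step_s=5.0, nw=3.0, k=5)
    assert est.values.shape[0] == 8
    # windows aligned one segment apart see identical data
    np.testing.assert_allclose(est.values[0], est.values[2], rtol=1e-9)
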