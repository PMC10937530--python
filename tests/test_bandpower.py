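import numpy as np
import pytest
from scipy import signal as sps

from cogload.bandpower import (
    ALPHA,
    THETA,
    TOTAL,
    BandDef,
    band_fraction,
    first_order_series,
    integrate_band,
    sliding_psd,
)
from cogload.io import MultiChannelRecording
from tests.conftest import make_eeg


class TestSlidingPsd:
    @pytest.mark.parametrize("duration_s,expected", [(300, 281), (20, 1), (41, 22)])
    def test_window_count(self, duration_s, expected):
        rec = make_eeg(lambda t: np.sin(2 * np.pi * 10 * t), duration_s=duration_s,
                       n_channels=1)
        _, psd, _ = sliding_psd(rec)
        assert psd.shape[0] == expected

    def test_too_short_raises(self):
        rec = make_eeg(lambda t: t * 0, duration_s=10, n_channels=1)
        with pytest.raises(ValueError, match="shorter"):
            sliding_psd(rec)

    def test_sinusoid_power_concentrates_at_its_bin(self):
        rec = make_eeg(lambda t: np.sin(2 * np.pi * 10 * t), duration_s=40,
                       n_channels=1)
        freqs, psd, _ = sliding_psd(rec)
        peak_bin = np.argmax(psd[0, :, 0])
        assert freqs[peak_bin] == pytest.approx(10.0)
        # >90% of total power within 10 +/- 1 Hz in every window
        near = np.abs(freqs - 10.0) <= 1.0
        frac = psd[:, near, 0].sum(axis=1) / psd[:, :, 0].sum(axis=1)
        assert np.all(frac > 0.9)

    def test_rolling_average_equals_direct_welch(self):
        """The shared-segment fast path reproduces scipy's Welch per window."""
        rng = np.random.default_rng(11)
        rec = MultiChannelRecording(rng.standard_normal((30 * 256, 2)), 256.0,
                                    ("F3", "F4"))
        freqs, psd, _ = sliding_psd(rec)
        for k in (0, 5, 10):
            seg = rec.samples[k * 256 : k * 256 + 20 * 256]
            f_ref, p_ref = sps.welch(seg, fs=256.0, window="hann", nperseg=256,
                                     noverlap=0, axis=0)
            np.testing.assert_allclose(freqs, f_ref)
            np.testing.assert_allclose(psd[k], p_ref, rtol=1e-8, atol=1e-12)


class TestBandFraction:
    def test_pure_alpha_tone(self):
        rec = make_eeg(lambda t: np.sin(2 * np.pi * 10 * t), duration_s=30,
                       n_channels=1)
        freqs, psd, _ = sliding_psd(rec)
        frac = band_fraction(freqs, psd[0, :, 0], ALPHA)
        assert frac >= 0.95

    def test_out_of_band_tone(self):
        rec = make_eeg(lambda t: np.sin(2 * np.pi * 20 * t), duration_s=30,
                       n_channels=1)
        freqs, psd, _ = sliding_psd(rec)
        assert band_fraction(freqs, psd[0, :, 0], ALPHA) <= 0.05

    def test_flat_spectrum_gives_bandwidth_ratio(self):
        freqs = np.arange(0.0, 129.0)
        psd = np.ones_like(freqs)
        assert band_fraction(freqs, psd, ALPHA) == pytest.approx(5 / 26, abs=1e-12)
        assert band_fraction(freqs, psd, THETA) == pytest.approx(3 / 26, abs=1e-12)

    def test_zero_power_yields_nan(self):
        freqs = np.arange(0.0, 129.0)
        assert np.isnan(band_fraction(freqs, np.zeros_like(freqs), ALPHA))

    def test_integrate_band_edge_interpolation(self):
        # linear PSD -> trapezoid with interpolated edges is exact
        freqs = np.arange(0.0, 129.0)
        psd = 2.0 * freqs
        got = integrate_band(freqs, psd, 8.5, 12.5)
        assert got == pytest.approx((12.5**2 - 8.5**2), rel=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDef("bad", 13.0, 8.0)


class TestFirstOrderSeries:
    def test_stationary_alpha_is_nearly_constant(self):
        rng = np.random.default_rng(12)
        t = np.arange(300 * 256) / 256.0
        x = np.sin(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(len(t))
        rec = MultiChannelRecording(np.tile(x[:, None], (1, 6)), 256.0,
                                    ("AF3", "AF4", "F3", "F4", "F7", "F8"))
        series = first_order_series(rec, ALPHA)
        cv = series.values[:, 0].std() / series.values[:, 0].mean()
        assert cv < 0.1
        assert series.n_windows == 281

    def test_modulated_alpha_series_oscillates_at_modulation_rate(self):
        t = np.arange(600 * 256) / 256.0
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.01 * t)
        x = env * np.sin(2 * np.pi * 10 * t) + 0.3 * np.sin(2 * np.pi * 20 * t)
        rec = MultiChannelRecording(x[:, None], 256.0, ("F3",))
        series = first_order_series(rec, ALPHA)
        v = series.values[:, 0] - series.values[:, 0].mean()
        spec = np.abs(np.fft.rfft(v * np.hanning(len(v))))
        freqs = np.fft.rfftfreq(len(v), d=1.0)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(0.01, abs=0.003)

    def test_scale_invariance(self, alpha_series, modulated_eeg):
        from dataclasses import replace

        from cogload.preprocess import bandpass, remove_offset

        scaled = replace(modulated_eeg, samples=7.3 * modulated_eeg.samples)
        series2 = first_order_series(bandpass(remove_offset(scaled)), ALPHA)
        np.testing.assert_allclose(series2.values, alpha_series.values, rtol=1e-9)

    def test_alpha_plus_theta_fractions_bounded(self, alpha_series, modulated_eeg):
        from cogload.preprocess import bandpass, remove_offset

        rec = bandpass(remove_offset(modulated_eeg))
        theta = first_order_series(rec, THETA)
        total = alpha_series.values + theta.values
        assert np.all(alpha_series.values >= 0) and np.all(alpha_series.values <= 1)
        assert np.all(total <= 1.0 + 1e-9)

    def test_alpha_amplitude_monotonicity(self):
        """More alpha at fixed broadband noise raises the alpha fraction."""
        from cogload.synthdata import synth_eeg

        fracs = []
        for amp in (5.0, 10.0, 20.0):
            rec = synth_eeg(duration_s=60.0, alpha_amp=amp, modulation_depth=0.0,
                            envelope_noise_sd=0.0, seed=42)
            series = first_order_series(rec, ALPHA)
            fracs.append(series.values.mean())
        assert fracs[0] < fracs[1] < fracs[2]


def test_power_series_frame_long_format(alpha_series):
    from cogload.bandpower import power_series_frame

    frame = power_series_frame(alpha_series)
    assert list(frame.columns) == ["time_s", "channel", "band", "fraction"]
    assert len(frame) == alpha_series.n_windows * 6
    assert set(frame.band) == {"alpha"}
    sub = frame[frame.channel == "AF3"]
    np.testing.assert_allclose(sub.fraction.to_numpy(), alpha_series.values[:, 0])
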