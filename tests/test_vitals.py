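"""Rate estimation: separation, filters, spectral zoom, decision rule."""

import numpy as np
import pytest

from radarvitals import (
    SpectrumEstimate,
    bandpass_heart,
    decide_heart_rate,
    fft_confidence,
    fft_czt_rate,
    fft_spectrum,
    notch_harmonics,
    peak_seek_rate,
    relative_error,
    separate_vitals,
    snr_metric,
)
from radarvitals.vitals import extract_heart_waveform, peak_interval_rate

FS = 20.0


def tone(f, n=256, a=1.0, fs=FS, phase=0.0):
    return a * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


class TestSeparateVitals:
    def test_two_tone_phase_signal_split_into_bands(self):
        x = tone(0.3, a=1.0) + tone(1.2, a=0.4)
        breathing, heart = separate_vitals(x, fs=FS)
        for out, src in ((breathing, tone(0.3)), (heart, tone(1.2, a=0.4))):
            assert np.corrcoef(out, src)[0, 1] >= 0.9
        # dominant frequencies inside the assigned bands
        fb = fft_spectrum(breathing, FS).peak_freq
        fh = fft_spectrum(heart, FS).peak_freq
        assert abs(fb - 0.3) < 0.05
        assert abs(fh - 1.2) < 0.05

    def test_zero_input_has_no_assignable_modes(self):
        with pytest.raises(ValueError, match="band"):
            separate_vitals(np.zeros(256), fs=FS)


class TestBandpassHeart:
    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_heart(np.zeros(256), FS), 0)

    def test_passband_tone_preserved_within_ripple(self):
        x = tone(1.2, n=2048)
        y = bandpass_heart(x, FS)
        mid = slice(512, 1536)  # avoid transients
        gain = np.max(np.abs(y[mid]))
        # zero-phase application doubles the 0.5 dB design ripple
        assert gain > 10 ** (-1.0 / 20)
        assert gain < 1.05

    def test_stopband_tone_attenuated(self):
        x = tone(0.25, n=4096)
        y = bandpass_heart(x, FS)
        mid = slice(1024, 3072)
        assert np.max(np.abs(y[mid])) < 10 ** (-40 / 20)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_heart(np.zeros(100), fs=6.0)


class TestNotchHarmonics:
    def test_second_harmonic_attenuated(self):
        f_resp = 0.4
        x = tone(2 * f_resp, n=4096)
        y = notch_harmonics(x, FS, f_resp)
        mid = slice(1024, 3072)
        assert np.max(np.abs(y[mid])) < 10 ** (-20 / 20)

    def test_off_harmonic_tone_untouched(self):
        f_resp = 0.4
        x = tone(1.3 * f_resp, n=4096)
        y = notch_harmonics(x, FS, f_resp)
        mid = slice(1024, 3072)
        assert np.max(np.abs(y[mid])) > 10 ** (-1 / 20)

    def test_zero_in_zero_out(self):
        assert np.allclose(notch_harmonics(np.zeros(128), FS, 0.3), 0)

    def test_notch_above_nyquist_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            out = notch_harmonics(tone(1.0), FS, 3.0)  # 4x = 12 Hz > 10
        assert out.shape == (256,)


class TestFftCzt:
    def test_fine_peak_on_pure_tone(self):
        x = tone(0.30)
        est = fft_czt_rate(x, FS, (0.1, 0.7))
        assert est.method == "fft_czt"
        assert abs(est.peak_freq - 0.30) < 0.002

    def test_refinement_stays_within_one_bin_of_coarse_peak(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            f = rng.uniform(0.8, 3.0)
            x = tone(f) + 0.1 * rng.normal(size=256)
            est = fft_czt_rate(x, FS, (0.7, 3.3))
            freqs = np.fft.rfftfreq(256, 1 / FS)
            amps = np.abs(np.fft.rfft(x))
            mask = (freqs >= 0.7) & (freqs <= 3.3)
            coarse = freqs[mask][np.argmax(amps[mask])]
            assert abs(est.peak_freq - coarse) <= FS / 256

    def test_stronger_tone_wins(self):
        x = tone(1.0, a=2.0) + tone(2.0, a=1.0)
        est = fft_czt_rate(x, FS, (0.7, 3.3))
        assert abs(est.peak_freq - 1.0) < 0.05

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            fft_czt_rate(tone(1.0), FS, (5.0, 4.0))
        with pytest.raises(ValueError):
            fft_czt_rate(tone(1.0), FS, (0.0, 0.01))


class TestPeakSeeking:
    def test_rate_arithmetic(self):
        # 16 counted peaks over 12.8 s -> 1.25 Hz
        x = tone(1.25, n=256)
        n_p, fh = peak_seek_rate(x, FS, duration=12.8)
        assert n_p == 16
        assert fh == pytest.approx(1.25)

    def test_isolated_spike_not_counted(self):
        x = np.zeros(64)
        x[30] = 5.0  # neighbours are flat: fails the outer conditions
        n_p, _ = peak_seek_rate(x, FS)
        assert n_p == 0

    def test_spike_on_noise_floor_not_counted(self):
        x = np.array([0.0, 0.2, 0.1, 5.0, 0.1, 0.2, 0.0, 0.0])
        # left neighbour 0.1 < 0.2 breaks monotone descent
        n_p, _ = peak_seek_rate(x, FS)
        assert n_p == 0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            peak_seek_rate(np.ones(4), FS)

    def test_interval_rate_not_quantised_to_window(self):
        f = 1.3
        x = tone(f, n=256, phase=0.4)
        _, f_int = peak_interval_rate(x, FS)
        assert abs(f_int - f) < 0.02
        # the count-based rate is quantised to 1/12.8 ~ 0.078
        _, f_cnt = peak_seek_rate(x, FS)
        assert abs(f_cnt * 12.8 - round(f_cnt * 12.8)) < 1e-9

    def test_heart_waveform_extraction_cleans_peek(self):
        rng = np.random.default_rng(1)
        x = tone(1.2, a=0.5) + 0.25 * rng.normal(size=256)
        filtered = bandpass_heart(x, FS)
        wave = extract_heart_waveform(filtered, FS)
        _, f_int = peak_interval_rate(wave, FS)
        assert abs(f_int - 1.2) < 0.05


class TestConfidence:
    def test_uniform_spectrum_value(self):
        m = 64
        spec = SpectrumEstimate(freqs=np.arange(m) * 0.1 + 0.1,
                                amps=np.ones(m), peak_freq=0.1, method="fft")
        assert fft_confidence(spec) == pytest.approx(3 / (m - 3))

    def test_all_energy_in_peak_hits_sentinel_cap(self):
        amps = np.zeros(16)
        amps[7:10] = [0.5, 1.0, 0.5]  # peak line 8 plus its two neighbours
        spec = SpectrumEstimate(freqs=np.arange(16) * 0.1 + 0.1,
                                amps=amps, peak_freq=0.9, method="fft")
        assert fft_confidence(spec) >= 1e12

    def test_tone_more_confident_than_white_noise(self):
        rng = np.random.default_rng(2)
        x_tone = tone(1.2) * np.hanning(256)
        noise = rng.normal(size=256)
        noise *= np.linalg.norm(x_tone) / np.linalg.norm(noise)
        s_tone = fft_confidence(fft_spectrum(x_tone, FS))
        s_noise = fft_confidence(fft_spectrum(noise, FS))
        assert s_tone > s_noise

    def test_tiny_spectrum_rejected(self):
        spec = SpectrumEstimate(freqs=np.array([0.1, 0.2, 0.3]),
                                amps=np.ones(3), peak_freq=0.1, method="fft")
        with pytest.raises(ValueError):
            fft_confidence(spec)


class TestDecision:
    def test_confident_and_close_uses_spectral_estimate(self):
        d = decide_heart_rate(1.20, 1.25, s_fft=2.0,
                              conf_threshold=1.0, diff_threshold=0.1)
        assert d.chosen == "fft_czt" and d.final == 1.20

    def test_low_confidence_falls_back_to_peek(self):
        d = decide_heart_rate(1.20, 1.25, s_fft=0.5,
                              conf_threshold=1.0, diff_threshold=0.1)
        assert d.chosen == "peek" and d.final == 1.25

    def test_disagreement_falls_back_to_peek(self):
        d = decide_heart_rate(1.20, 1.45, s_fft=5.0,
                              conf_threshold=1.0, diff_threshold=0.1)
        assert d.chosen == "peek" and d.final == 1.45

    def test_printed_worked_example_selects_peek(self):
        """66 bpm subject at 0.8 m: estimates 1.0547 (spectral) and
        1.0989 (peek) with judgment 1.0989 -> the decision must route to
        peek, here via a sub-threshold confidence."""
        d = decide_heart_rate(1.0547, 1.0989, s_fft=0.2)
        assert d.chosen == "peek"
        assert d.final == 1.0989

    def test_pure_function_of_inputs(self):
        args = (1.3, 1.35, 0.9, 0.4, 0.1)
        assert decide_heart_rate(*args) == decide_heart_rate(*args)

    def test_non_finite_estimates_rejected(self):
        with pytest.raises(ValueError):
            decide_heart_rate(np.nan, 1.0, 1.0)


class TestMetrics:
    @pytest.mark.parametrize(
        "f_est,ref,expected",
        [(1.0989, 66, 0.10), (1.9373, 120, 3.14), (1.25, 75, 0.0)],
    )
    def test_relative_error_worked_examples(self, f_est, ref, expected):
        assert abs(relative_error(f_est, ref) - expected) <= 0.005 + 1e-9

    def test_relative_error_rejects_bad_reference(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)

    def test_snr_equal_split_is_zero_db(self):
        amps = np.ones(8)
        amps[3:6] = np.sqrt(5 / 3)  # E3 = 5, rest = 5
        spec = SpectrumEstimate(freqs=np.arange(8) + 1.0, amps=amps,
                                peak_freq=4.0, method="fft")
        assert snr_metric(spec, 4) == pytest.approx(0.0, abs=1e-12)

    def test_snr_uniform_spectrum(self):
        m = 32
        spec = SpectrumEstimate(freqs=np.arange(m) + 1.0, amps=np.ones(m),
                                peak_freq=1.0, method="fft")
        assert snr_metric(spec, 10) == pytest.approx(
            10 * np.log10(3 / (m - 3)))

    def test_snr_peak_at_edge_rejected(self):
        spec = SpectrumEstimate(freqs=np.arange(8) + 1.0, amps=np.ones(8),
                                peak_freq=1.0, method="fft")
        with pytest.raises(ValueError):
            snr_metric(spec, 0)
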