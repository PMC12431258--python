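"""Frame features (energy, entropy, ZCR, centroid) and Mel spectrograms."""

import numpy as np
import pytest

import snorescreen as ss
from snorescreen.errors import ValidationError
from snorescreen.features import (
    DEFAULT_ENTROPY_EPS,
    MelConfig,
    mel_filterbank,
    mel_to_hz,
)


class TestShortTimeEnergy:
    def test_zero_frame(self):
        assert ss.short_time_energy(np.zeros(10)) == 0.0

    def test_hand_sum(self):
        assert ss.short_time_energy([1.0, -1.0, 2.0]) == 6.0

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        for a in rng.uniform(0.1, 5, size=5):
            assert np.isclose(
                ss.short_time_energy(a * x), a**2 * ss.short_time_energy(x)
            )

    def test_empty_frame_rejected(self):
        with pytest.raises(ValidationError):
            ss.short_time_energy([])


class TestSpectralEntropy:
    def test_dc_frame_near_zero(self):
        k = 33  # one-sided bins of a 64-sample frame
        h = ss.spectral_entropy(np.ones(64) * 2.5)
        assert 0 <= h < 10 * DEFAULT_ENTROPY_EPS * k

    def test_impulse_frame_is_flat_spectrum(self):
        x = np.zeros(64)
        x[0] = 1.0
        k = 33
        assert np.isclose(ss.spectral_entropy(x), np.log(k), atol=1e-4)

    def test_white_noise_exceeds_tone_on_average(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(100):
            noise = rng.standard_normal(256)
            phase = rng.uniform(0, 2 * np.pi)
            tone = np.sqrt(2) * np.cos(
                2 * np.pi * rng.integers(4, 100) / 256 * np.arange(256) + phase
            )
            tone *= np.sqrt(np.sum(noise**2) / np.sum(tone**2))  # equal energy
            diffs.append(ss.spectral_entropy(noise) - ss.spectral_entropy(tone))
        assert np.mean(diffs) > 0

    def test_bounds_on_fuzzed_frames(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(8, 256))
            x = rng.standard_normal(n) * 10 ** rng.uniform(-6, 3)
            h = ss.spectral_entropy(x)
            assert 0.0 <= h <= np.log(n // 2 + 1)


class TestZeroCrossingRate:
    def test_constant_positive_frame(self):
        assert ss.zero_crossing_rate(np.full(50, 0.3)) == 0.0

    def test_alternating_frame_closed_form(self):
        n = 80
        x = np.tile([1.0, -1.0], n // 2)
        assert np.isclose(ss.zero_crossing_rate(x), (n - 1) / n)

    def test_matches_brute_force_sign_count(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(2, 64))
            x = rng.standard_normal(n)
            x[rng.uniform(size=n) < 0.1] = 0.0  # exercise sgn(0) = +1
            sgn = [1.0 if v >= 0 else -1.0 for v in x]
            brute = sum(abs(sgn[i] - sgn[i - 1]) for i in range(1, n)) / (2 * n)
            assert np.isclose(ss.zero_crossing_rate(x), brute, rtol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        assert ss.zero_crossing_rate(x) == ss.zero_crossing_rate(7.3 * x)

    def test_short_frame_rejected(self):
        with pytest.raises(ValidationError):
            ss.zero_crossing_rate([1.0])


class TestSpectralCentroid:
    def test_pure_tone_converges_to_its_frequency(self):
        rate = 16000
        for n, tol in [(400, 250.0), (4096, 30.0)]:
            t = np.arange(n) / rate
            c = ss.spectral_centroid(np.sin(2 * np.pi * 1000 * t), rate)
            assert abs(c - 1000.0) < tol

    def test_symmetric_spectrum_centroid_at_centre(self):
        n, rate = 256, 16000
        spec = np.zeros(n // 2 + 1)
        spec[40] = spec[60] = 1.0
        spec[50] = 2.0
        x = np.fft.irfft(spec, n)
        freqs = np.fft.rfftfreq(n, 1 / rate)
        assert np.isclose(ss.spectral_centroid(x, rate), freqs[50], rtol=1e-6)

    def test_white_noise_centroid_near_half_nyquist(self):
        rng = np.random.default_rng(5)
        cs = [ss.spectral_centroid(rng.standard_normal(512), 16000) for _ in range(100)]
        assert abs(np.mean(cs) - 4000.0) < 0.05 * 4000.0

    def test_all_zero_frame_returns_zero(self):
        assert ss.spectral_centroid(np.zeros(64), 16000) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(128)
        assert np.isclose(
            ss.spectral_centroid(x, 16000), ss.spectral_centroid(4 * x, 16000)
        )


class TestFeatureTable:
    def test_all_zero_frame_conventions(self):
        sig = ss.AudioSignal(np.zeros(16000) + 0.0, 16000)
        sig = ss.AudioSignal(np.concatenate([np.zeros(400)]), 16000)
        table = ss.compute_feature_table(ss.frame_signal(sig))
        assert table.energy[0] == 0.0
        assert table.zcr[0] == 0.0
        assert table.centroid[0] == 0.0
        assert np.isclose(table.entropy[0], np.log(201))  # K = 400 // 2 + 1
        assert not table.valid[0]

    def test_table_length_equals_frame_count(self):
        rng = np.random.default_rng(7)
        sig = ss.AudioSignal(rng.standard_normal(12345), 16000)
        frames = ss.frame_signal(sig)
        table = ss.compute_feature_table(frames)
        assert len(table) == frames.n_frames

    def test_columns_match_scalar_operations(self):
        rng = np.random.default_rng(8)
        sig = ss.AudioSignal(rng.standard_normal(8400), 16000)
        frames = ss.frame_signal(sig)
        table = ss.compute_feature_table(frames)
        for i in range(min(50, frames.n_frames)):
            f = frames.frames[i]
            assert np.isclose(table.energy[i], ss.short_time_energy(f), rtol=1e-12)
            assert np.isclose(table.entropy[i], ss.spectral_entropy(f), rtol=1e-9)
            assert np.isclose(table.zcr[i], ss.zero_crossing_rate(f), rtol=1e-12)
            assert np.isclose(
                table.centroid[i], ss.spectral_centroid(f, 16000), rtol=1e-9
            )


class TestMelMapping:
    def test_zero_maps_to_zero_in_both_variants(self):
        assert ss.hz_to_mel(0.0, "paper") == 0.0
        assert ss.hz_to_mel(0.0, "htk_standard") == 0.0

    def test_printed_and_standard_denominators(self):
        assert np.isclose(ss.hz_to_mel(100.0, "paper"), 2595 * np.log10(2))
        assert np.isclose(ss.hz_to_mel(700.0, "htk_standard"), 2595 * np.log10(2))

    @pytest.mark.parametrize("variant", ["paper", "htk_standard"])
    def test_strictly_increasing_and_invertible(self, variant):
        f = np.linspace(0, 24000, 2000)
        m = ss.hz_to_mel(f, variant)
        assert np.all(np.diff(m) > 0)
        assert np.allclose(mel_to_hz(m, variant), f, rtol=1e-9, atol=1e-6)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ss.hz_to_mel(-1.0)


class TestMelFilterbank:
    @pytest.mark.parametrize("variant", ["paper", "htk_standard"])
    def test_no_all_zero_filter_and_coverage(self, variant):
        fb = mel_filterbank(128, 2048, 16000, variant)
        assert fb.shape == (128, 1025)
        assert np.all(fb.sum(axis=1) > 0)
        assert np.all(fb >= 0)

    def test_per_bin_weights_sum_at_most_one(self):
        fb = mel_filterbank(128, 2048, 16000)
        assert np.all(fb.sum(axis=0) <= 1.0 + 1e-9)


class TestMelSpectrogram:
    @pytest.mark.parametrize("duration", [0.5, 1.0, 3.0])
    def test_output_always_128_by_128(self, duration, make_tone):
        mel = ss.mel_spectrogram(make_tone(300.0, duration))
        assert mel.matrix.shape == (128, 128)

    def test_mel_energy_bounded_by_spectral_energy(self):
        rng = np.random.default_rng(9)
        cfg = MelConfig(log_scale=False, target_frames=128)
        for _ in range(5):
            clip = ss.AudioSignal(rng.standard_normal(16000), 16000)
            hop = int(16000 * cfg.hop_ms / 1000)
            n_frames = (16000 - cfg.n_fft) // hop + 1
            idx = np.arange(cfg.n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
            from scipy.signal.windows import hamming

            power = np.abs(
                np.fft.rfft(clip.samples[idx] * hamming(cfg.n_fft, sym=False), axis=1)
            ) ** 2
            fb = mel_filterbank(cfg.n_mels, cfg.n_fft, 16000)
            assert (fb @ power.T).sum() <= power.sum() * (1 + 1e-9)

    def test_tone_frequency_ordering_on_mel_axis(self, make_tone):
        low = ss.mel_spectrogram(make_tone(200.0, 1.0))
        high = ss.mel_spectrogram(make_tone(4000.0, 1.0))
        assert np.argmax(low.matrix.sum(axis=1)) < np.argmax(high.matrix.sum(axis=1))

    def test_short_clip_rejected(self):
        with pytest.raises(ValidationError):
            ss.mel_spectrogram(ss.AudioSignal(np.ones(100), 16000))

    def test_short_clip_padding_flagged(self, make_tone):
        mel = ss.mel_spectrogram(make_tone(300.0, 0.5))
        assert mel.padded
        assert mel.matrix.shape == (128, 128)
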