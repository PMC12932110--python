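import numpy as np
import pytest

from specmotion import speech
from specmotion.speech import (BinarizedSpectrogram, Spectrogram,
                               binarize_otsu, compute_spectrogram,
                               continuous_hrc_signals,
                               correlate_with_tone_change,
                               estimate_tone_change, pattern_net_signals)
from specmotion.synthesis import Waveform


def _tone(freq, duration=1.0, fs=16000):
    t = np.arange(round(duration * fs)) / fs
    return Waveform(np.sin(2 * np.pi * freq * t), fs)


class TestSpectrogram:
    def test_pure_tone_peaks_at_its_frequency(self):
        spec = compute_spectrogram(_tone(800.0))
        target = np.argmin(np.abs(spec.freqs - 800.0))
        peaks = spec.A.argmax(axis=0)
        assert np.all(np.abs(peaks - target) <= 1)

    def test_exact_method_agrees_with_fft_interpolation(self):
        wave = _tone(800.0, duration=0.5)
        a = compute_spectrogram(wave, method="fft")
        b = compute_spectrogram(wave, method="exact")
        # same argmax row in every frame
        np.testing.assert_array_equal(a.A.argmax(axis=0), b.A.argmax(axis=0))

    def test_silence_is_near_zero(self):
        wave = Waveform(np.zeros(16000), 16000)
        spec = compute_spectrogram(wave)
        assert spec.A.max() < 1e-3  # below -60 dB of full scale

    def test_one_second_gives_40_frames(self):
        spec = compute_spectrogram(_tone(500.0, duration=1.0))
        assert spec.n_frames == 40
        assert spec.freqs.size == 121  # 20 steps/octave over 100-6400 Hz

    def test_short_audio_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(Waveform(np.zeros(100), 16000))

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(Waveform(np.zeros(8000), 8000))


class TestToneChange:
    def _chirp_spectrogram(self, rising=True):
        # deterministic synthetic spectrogram: a band climbing one row/frame
        n_f, n_t = 60, 40
        A = np.zeros((n_f, n_t))
        for j in range(n_t):
            row = 10 + j // 2 if rising else 50 - j // 2
            A[row - 2:row + 3, j] = 1.0
        freqs = speech.log_frequency_axis()[:n_f]
        return Spectrogram(A, freqs, 40.0)

    def test_rising_chirp_positive(self):
        tone = estimate_tone_change(self._chirp_spectrogram(rising=True))
        assert tone.mean() > 0

    def test_constant_tone_near_zero(self):
        n_f, n_t = 40, 30
        A = np.zeros((n_f, n_t))
        A[20] = 1.0
        tone = estimate_tone_change(Spectrogram(A, speech.log_frequency_axis()[:n_f], 40.0))
        np.testing.assert_allclose(tone, 0.0, atol=1e-10)

    def test_frequency_mirror_negates_flow(self):
        spec = self._chirp_spectrogram(rising=True)
        mirrored = Spectrogram(spec.A[::-1], spec.freqs, spec.frame_rate)
        a = estimate_tone_change(spec)
        b = estimate_tone_change(mirrored)
        np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_all_zero_spectrogram_returns_zeros(self):
        spec = Spectrogram(np.zeros((10, 5)), speech.log_frequency_axis()[:10], 40.0)
        np.testing.assert_array_equal(estimate_tone_change(spec), 0.0)

    def test_single_frame_rejected(self):
        spec = Spectrogram(np.ones((10, 1)), speech.log_frequency_axis()[:10], 40.0)
        with pytest.raises(ValueError):
            estimate_tone_change(spec)


class TestOtsu:
    def test_two_level_grid_recovered_exactly(self):
        rng = np.random.default_rng(3)
        truth = rng.random((30, 30)) > 0.6
        A = np.where(truth, 0.9, 0.2)
        spec = Spectrogram(A, speech.log_frequency_axis()[:30], 40.0)
        b = binarize_otsu(spec)
        assert 0.2 < b.threshold < 0.9
        np.testing.assert_array_equal(b.mask, truth)

    def test_threshold_matches_brute_force_scan(self):
        # oracle: exhaustive search of between-class variance over 256 bins
        rng = np.random.default_rng(5)
        A = rng.gamma(2.0, 1.0, size=(40, 50))
        spec = Spectrogram(A, speech.log_frequency_axis()[:40], 40.0)
        thr = binarize_otsu(spec).threshold

        counts, edges = np.histogram(A, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_var = None, -1.0
        total = counts.sum()
        for k in range(1, 256):
            w0 = counts[:k].sum() / total
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (counts[:k] * centers[:k]).sum() / counts[:k].sum()
            mu1 = (counts[k:] * centers[k:]).sum() / counts[k:].sum()
            var = w0 * w1 * (mu0 - mu1) ** 2
            if var > best_var:
                best_var, best = var, centers[k - 1]
        assert thr == pytest.approx(best, abs=(edges[1] - edges[0]) * 1.5)

    def test_constant_input_rejected(self):
        spec = Spectrogram(np.ones((10, 10)), speech.log_frequency_axis()[:10], 40.0)
        with pytest.raises(ValueError):
            binarize_otsu(spec)


class TestPatternNets:
    def _binarized(self, mask):
        return BinarizedSpectrogram(mask, 0.5, speech.log_frequency_axis()[:mask.shape[0]], 40.0)

    def test_four_traces_sum_to_zero(self):
        rng = np.random.default_rng(7)
        sig = pattern_net_signals(self._binarized(rng.random((25, 40)) > 0.5))
        # exact at the integer grid level; traces only up to float rounding
        grid_total = sum(sig.net_grids[p] for p in speech.SIGN_PATTERNS)
        np.testing.assert_array_equal(grid_total, 0)
        total = sum(sig.traces[p] for p in speech.SIGN_PATTERNS)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_all_true_grid_has_no_net(self):
        sig = pattern_net_signals(self._binarized(np.ones((10, 10), dtype=bool)))
        for p in speech.SIGN_PATTERNS:
            np.testing.assert_array_equal(sig.net_grids[p], 0)

    def test_ascending_staircase_drives_hh_up(self):
        n = 12
        mask = np.zeros((n, n), dtype=bool)
        mask[np.arange(n), np.arange(n)] = True
        sig = pattern_net_signals(self._binarized(mask))
        assert sig.traces["HH"].sum() > 0
        assert sig.traces["HL"].sum() <= 0

    def test_frequency_mirror_negates_all_nets(self):
        rng = np.random.default_rng(11)
        mask = rng.random((20, 30)) > 0.4
        a = pattern_net_signals(self._binarized(mask))
        b = pattern_net_signals(self._binarized(mask[::-1]))
        for p in speech.SIGN_PATTERNS:
            np.testing.assert_array_equal(a.traces[p], -b.traces[p])


class TestContinuousHRC:
    def test_constant_spectrogram_silent(self):
        spec = Spectrogram(np.full((10, 10), 2.0), speech.log_frequency_axis()[:10], 40.0)
        sig = continuous_hrc_signals(spec)
        for p in speech.SIGN_PATTERNS:
            np.testing.assert_array_equal(sig.traces[p], 0.0)

    def test_rising_energy_ramp_drives_positive_pair(self):
        # direct evaluation oracle on a constructed upward-moving onset ramp
        n_f, n_t = 20, 30
        A = np.zeros((n_f, n_t))
        for j in range(n_t):
            A[: min(n_f, 2 + j), j] = 1.0  # energy front climbing in frequency
        spec = Spectrogram(A, speech.log_frequency_axis()[:n_f], 40.0)
        sig = continuous_hrc_signals(spec)
        assert sig.traces["HH"].sum() > 0

    def test_negative_derivatives_do_not_enter_positive_terms(self):
        # a purely decaying spectrogram has no (+,+) signal at all
        n_f, n_t = 10, 20
        A = np.linspace(1.0, 0.0, n_t)[None, :] * np.ones((n_f, 1))
        spec = Spectrogram(A, speech.log_frequency_axis()[:n_f], 40.0)
        sig = continuous_hrc_signals(spec)
        np.testing.assert_array_equal(sig.traces["HH"], 0.0)

    def test_too_few_frames_rejected(self):
        spec = Spectrogram(np.ones((5, 2)), speech.log_frequency_axis()[:5], 40.0)
        with pytest.raises(ValueError):
            continuous_hrc_signals(spec)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(13)
        trace = rng.normal(size=100)
        sig = speech.PatternSignal({}, {p: trace for p in speech.SIGN_PATTERNS}, 40.0)
        r = correlate_with_tone_change(sig, trace)
        for p in speech.SIGN_PATTERNS:
            assert r[p] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(17)
        n = 4000
        sig = speech.PatternSignal(
            {}, {p: rng.normal(size=n) for p in speech.SIGN_PATTERNS}, 40.0)
        r = correlate_with_tone_change(sig, rng.normal(size=n))
        for p in speech.SIGN_PATTERNS:
            assert abs(r[p]) < 3 / np.sqrt(n)

    def test_too_few_frames_rejected(self):
        sig = speech.PatternSignal({}, {p: np.ones(2) for p in speech.SIGN_PATTERNS}, 40.0)
        with pytest.raises(ValueError):
            correlate_with_tone_change(sig, np.ones(2))


class TestChirpCorpusSignStructure:
    def _pooled(self, chirp_spectrograms, pipeline):
        tones, traces = [], {p: [] for p in speech.SIGN_PATTERNS}
        for _, spec in chirp_spectrograms:
            tone = estimate_tone_change(spec)
            if pipeline == "digital":
                sig = pattern_net_signals(binarize_otsu(spec))
            else:
                sig = continuous_hrc_signals(spec)
            n = min(tone.size, sig.traces["HH"].size)
            tones.append(tone[:n])
            for p in speech.SIGN_PATTERNS:
                traces[p].append(sig.traces[p][:n])
        pooled = speech.PatternSignal(
            {}, {p: np.concatenate(traces[p]) for p in speech.SIGN_PATTERNS}, 40.0)
        return correlate_with_tone_change(pooled, np.concatenate(tones))

    @pytest.mark.parametrize("pipeline", ["digital", "continuous"])
    def test_positive_patterns_track_tone_change(self, chirp_spectrograms, pipeline):
        r = self._pooled(chirp_spectrograms, pipeline)
        assert r["HH"] > 0 and r["LL"] > 0
        assert r["HL"] < 0 and r["LH"] < 0
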