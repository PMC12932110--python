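"""Audio synthesis: carrier comb, loudness weights, envelopes and WAV I/O.

A stimulus waveform is a sum of enveloped sinusoids

    w(t) = sum_i  theta_i * m_i(t) * sin(2 pi f_i t)

where the f_i form a log-spaced carrier comb, the m_i(t) are the mask-derived
amplitude envelopes, and the theta_i are equal-loudness weights that roughly
equalize the perceptual salience of the carriers (ISO 226 contour at
60 phon by default).  The default sampling rate is 20 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from .masks import CoarseMask, FineMask, FrequencyGrid

__all__ = [
    "EnvelopeSet",
    "LoudnessWeights",
    "Waveform",
    "DEFAULT_FS",
    "loudness_weights",
    "equal_loudness_spl",
    "upsample_smooth",
    "render_waveform",
    "write_wav",
    "read_wav",
]

DEFAULT_FS = 20_000

# ISO 226 equal-loudness parameters: frequency (Hz), exponent af,
# magnitude of linear transfer function Lu (dB), hearing threshold Tf (dB SPL).
_ISO226_F = np.array([
    20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500,
    630, 800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000,
    10000, 12500])
_ISO226_AF = np.array([
    0.532, 0.506, 0.480, 0.455, 0.432, 0.409, 0.387, 0.367, 0.349, 0.330,
    0.315, 0.301, 0.288, 0.276, 0.267, 0.259, 0.253, 0.250, 0.246, 0.244,
    0.243, 0.243, 0.243, 0.242, 0.242, 0.245, 0.254, 0.271, 0.301])
_ISO226_LU = np.array([
    -31.6, -27.2, -23.0, -19.1, -15.9, -13.0, -10.3, -8.1, -6.2, -4.5,
    -3.1, -2.0, -1.1, -0.4, 0.0, 0.3, 0.5, 0.0, -2.7, -4.1, -1.0, 1.7,
    2.5, 1.2, -2.1, -7.1, -11.2, -10.7, -3.1])
_ISO226_TF = np.array([
    78.5, 68.7, 59.5, 51.1, 44.0, 37.5, 31.5, 26.5, 22.1, 17.9, 14.4,
    11.4, 8.6, 6.2, 4.4, 3.0, 2.2, 2.4, 3.5, 1.7, -1.3, -4.2, -6.0,
    -5.4, -1.5, 6.0, 12.6, 13.9, 12.3])


@dataclass
class LoudnessWeights:
    """Per-carrier amplitude weights theta_i, normalized to 1 at 1 kHz."""

    weights: np.ndarray
    phon_level: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (np.isfinite(self.weights).all() and (self.weights > 0).all()):
            raise ValueError("loudness weights must be positive and finite")


@dataclass
class EnvelopeSet:
    """Per-carrier amplitude envelopes m_i(t) at audio rate."""

    envelopes: np.ndarray  # (n_carriers, n_samples)
    fs: float
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.envelopes.ndim != 2:
            raise ValueError("envelopes must be a 2-D array")
        if self.envelopes.min() < -1e-9 or self.envelopes.max() > 1 + 1e-9:
            raise ValueError("envelope values must lie in [0, 1]")


@dataclass
class Waveform:
    """Mono or stereo audio; samples shaped (n,) or (n, 2), |samples| <= 1."""

    samples: np.ndarray
    fs: float
    norm_factor: float = 1.0  # peak amplitude before normalization

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("waveform is empty")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs


def equal_loudness_spl(freqs: np.ndarray, phon: float) -> np.ndarray:
    """Sound pressure level (dB SPL) at the given loudness level (phon).

    Evaluates the ISO 226 contour at the tabulated frequencies and
    interpolates in log-frequency.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.min() < _ISO226_F[0] or freqs.max() > _ISO226_F[-1]:
        raise ValueError("frequency outside the tabulated 20 Hz - 12.5 kHz range")
    af, lu, tf = _ISO226_AF, _ISO226_LU, _ISO226_TF
    a_f = (4.47e-3 * (10.0 ** (0.025 * phon) - 1.15)
           + (0.4 * 10.0 ** ((tf + lu) / 10.0 - 9.0)) ** af)
    spl_tab = 10.0 / af * np.log10(a_f) - lu + 94.0
    return np.interp(np.log2(freqs), np.log2(_ISO226_F), spl_tab)


def loudness_weights(grid: FrequencyGrid, phon: float = 60.0) -> LoudnessWeights:
    """Equal-loudness amplitude weights for the carrier comb.

    A carrier that requires a higher SPL to reach the target loudness level
    receives a proportionally larger amplitude; weights are normalized so
    the weight at 1 kHz equals 1.
    """
    spl = equal_loudness_spl(grid.carriers, phon)
    spl_ref = equal_loudness_spl(np.array([1000.0]), phon)[0]
    return LoudnessWeights(10.0 ** ((spl - spl_ref) / 20.0), phon)


def upsample_smooth(mask: CoarseMask | FineMask, fs: float = DEFAULT_FS,
                    cutoff_ms: float = 25.0,
                    grid: FrequencyGrid | None = None) -> EnvelopeSet:
    """Zero-order-hold upsample a mask to audio rate and smooth it.

    Smoothing is a linear-phase moving average of length ``cutoff_ms``
    (25 ms for the ternary correlated-noise stimuli, 0.5 ms for pip and
    binary stimuli, removing sharp envelope transitions); output values
    remain in [0, 1].
    """
    if fs <= 0 or cutoff_ms <= 0:
        raise ValueError("fs and cutoff_ms must be positive")
    period = mask.frame_duration if isinstance(mask, CoarseMask) else mask.sample_period
    rep = max(1, round(period * fs))
    env = np.repeat(np.asarray(mask.values, dtype=float), rep, axis=1)
    if env.min() < 0.0:
        raise ValueError("mask must be nonnegative (recentre before synthesis)")
    width = max(1, round(cutoff_ms / 1000.0 * fs))
    if width > 1:
        env = uniform_filter1d(env, size=width, axis=1, mode="nearest")
    env = np.clip(env, 0.0, 1.0)
    if grid is None:
        grid = FrequencyGrid()
    return EnvelopeSet(env, fs, grid)


def render_waveform(env: EnvelopeSet, weights: LoudnessWeights | None = None,
                    normalize: bool = True) -> Waveform:
    """Sum the weighted, enveloped carrier sinusoids into a mono waveform."""
    carriers = env.grid.carriers
    if env.envelopes.shape[0] != carriers.size:
        raise ValueError(
            f"{env.envelopes.shape[0]} envelopes for {carriers.size} carriers")
    if weights is not None and weights.weights.size != carriers.size:
        raise ValueError("weight count does not match carrier count")
    theta = np.ones(carriers.size) if weights is None else weights.weights
    t = np.arange(env.envelopes.shape[1]) / env.fs
    w = np.zeros(t.size)
    for th, m, f in zip(theta, env.envelopes, carriers):
        w += th * m * np.sin(2.0 * np.pi * f * t)
    peak = float(np.max(np.abs(w)))
    if normalize and peak > 0:
        w = w / peak
    return Waveform(w, env.fs, norm_factor=peak)


def stereo(left: Waveform, right: Waveform) -> Waveform:
    """Pair two mono waveforms into a stereo (binaural) waveform."""
    if left.samples.shape != right.samples.shape or left.fs != right.fs:
        raise ValueError("stereo channels must share length and sample rate")
    return Waveform(np.stack([left.samples, right.samples], axis=1), left.fs,
                    norm_factor=max(left.norm_factor, right.norm_factor))


def write_wav(path: str | Path, wave: Waveform, dtype: str = "pcm16") -> None:
    """Write a waveform as PCM 16-bit (default) or float32 WAV."""
    if dtype == "pcm16":
        data = np.round(np.clip(wave.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    elif dtype == "float32":
        data = wave.samples.astype(np.float32)
    else:
        raise ValueError("dtype must be 'pcm16' or 'float32'")
    wavfile.write(str(path), int(wave.fs), data)


def read_wav(path: str | Path) -> Waveform:
    """Read a WAV file back to float samples in [-1, 1]."""
    try:
        fs, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"not a readable WAV file: {path}") from exc
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 127.0
    else:
        samples = data.astype(float)
    return Waveform(samples, float(fs))
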