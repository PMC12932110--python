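"""Speech spectrotemporal-correlation pipeline.

The analysis asks whether local positive and negative intensity
correlations in a spectrogram carry the sign of ongoing pitch/intonation
change.  Stages:

1. ``compute_spectrogram`` — 25-ms non-overlapping frames, amplitudes at 20
   log-spaced frequencies per octave from 100 Hz to 6400 Hz (40 frames/s).
2. ``estimate_tone_change`` — Horn-Schunck optical flow along the frequency
   axis between consecutive frames, averaged over frequency: a
   model-agnostic per-frame scalar, positive for rising frequency content.
3. ``binarize_otsu`` — global Otsu threshold on the amplitudes.
4. ``pattern_net_signals`` — for each high/low intensity pair pattern
   (HH, LL, HL, LH) at adjacent frequency and the next frame, the count of
   upward-directed minus downward-directed occurrences, averaged over
   frequency.  The four net traces sum to zero at every frame.
5. ``continuous_hrc_signals`` — the non-binarized variant: temporal
   derivatives of the amplitudes feed a half-rectified
   Hassenstein-Reichardt correlator per sign pair.
6. ``correlate_with_tone_change`` — Pearson correlation of each net trace
   with the tone-change trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .synthesis import Waveform

__all__ = [
    "Spectrogram",
    "BinarizedSpectrogram",
    "PatternSignal",
    "SIGN_PATTERNS",
    "compute_spectrogram",
    "estimate_tone_change",
    "binarize_otsu",
    "pattern_net_signals",
    "continuous_hrc_signals",
    "correlate_with_tone_change",
]

SIGN_PATTERNS = ("HH", "LL", "HL", "LH")
_PATTERN_SIGNS = {"HH": (True, True), "LL": (False, False),
                  "HL": (True, False), "LH": (False, True)}


@dataclass
class Spectrogram:
    """Amplitude grid A (frequency rows x time frames) on a log-frequency axis."""

    A: np.ndarray
    freqs: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.freqs.size:
            raise ValueError("amplitude grid does not match the frequency axis")
        if self.A.min() < 0:
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]


@dataclass
class BinarizedSpectrogram:
    """Boolean grid plus the Otsu threshold that produced it."""

    mask: np.ndarray
    threshold: float
    freqs: np.ndarray
    frame_rate: float


@dataclass
class PatternSignal:
    """Net directional signals per intensity-pair pattern.

    ``net_grids[p]`` holds the per-(frame, frequency) net value (+1/0/-1
    for the binarized pipeline, continuous for the HRC variant);
    ``traces[p]`` is its frequency average per frame.
    """

    net_grids: dict[str, np.ndarray]
    traces: dict[str, np.ndarray]
    frame_rate: float


def log_frequency_axis(f_min: float = 100.0, f_max: float = 6400.0,
                       steps_per_octave: int = 20) -> np.ndarray:
    n_oct = np.log2(f_max / f_min)
    n = int(round(n_oct * steps_per_octave)) + 1
    return f_min * 2.0 ** (np.arange(n) / steps_per_octave)


def compute_spectrogram(wave: Waveform, frame_rate: float = 40.0,
                        f_min: float = 100.0, f_max: float = 6400.0,
                        steps_per_octave: int = 20,
                        method: str = "fft") -> Spectrogram:
    """Short-time spectral amplitude on a log-frequency axis.

    Non-overlapping frames of 1/frame_rate seconds (25 ms at the default
    40 frames/s).  ``method="fft"`` zero-pads each frame and interpolates
    the magnitude spectrum onto the log axis; ``method="exact"`` evaluates
    the discrete Fourier sum directly at each log-spaced frequency
    (Goertzel-style), trading speed for exactness off the FFT bin grid.
    """
    if wave.channels != 1:
        raise ValueError("speech analysis expects mono audio")
    fs = float(wave.fs)
    if fs < 2 * f_max:
        raise ValueError(f"sampling rate {fs} too low to resolve {f_max} Hz")
    frame_len = int(round(fs / frame_rate))
    x = np.asarray(wave.samples, dtype=float)
    n_frames = x.size // frame_len
    if n_frames < 1:
        raise ValueError("audio shorter than one analysis frame")
    frames = x[: n_frames * frame_len].reshape(n_frames, frame_len)
    freqs = log_frequency_axis(f_min, f_max, steps_per_octave)
    if method == "exact":
        t = np.arange(frame_len) / fs
        basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
        A = np.abs(basis @ frames.T) / frame_len
    elif method == "fft":
        n_fft = 1 << max(12, (4 * frame_len - 1).bit_length())
        mag = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) / frame_len
        fft_freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
        A = np.empty((freqs.size, n_frames))
        for j in range(n_frames):
            A[:, j] = np.interp(freqs, fft_freqs, mag[j])
    else:
        raise ValueError("method must be 'fft' or 'exact'")
    return Spectrogram(A, freqs, frame_rate)


def _horn_schunck_1d(i1: np.ndarray, i2: np.ndarray, alpha: float,
                     n_iter: int) -> np.ndarray:
    """Horn-Schunck flow between two 1-D images (here: spectrogram columns).

    Minimizes the brightness-constancy residual (I_f v + I_t)^2 plus
    alpha^2 |grad v|^2 by the standard Jacobi iteration; returns the
    per-position velocity along the frequency axis, positive toward higher
    indices (rising frequency).
    """
    i_t = i2 - i1
    i_f = np.gradient((i1 + i2) / 2.0)
    v = np.zeros_like(i1)
    denom = alpha ** 2 + i_f ** 2
    for _ in range(n_iter):
        v_bar = (np.roll(v, 1) + np.roll(v, -1)) / 2.0
        v_bar[0] = v[1] if v.size > 1 else v[0]
        v_bar[-1] = v[-2] if v.size > 1 else v[-1]
        v = v_bar - i_f * (i_f * v_bar + i_t) / denom
    return v


def estimate_tone_change(spec: Spectrogram, alpha: float = 1.0,
                         n_iter: int = 100) -> np.ndarray:
    """Per-frame tone change: frequency-averaged Horn-Schunck flow.

    Returns one scalar per consecutive frame pair (length n_frames - 1, in
    frequency steps per frame, arbitrary units); positive values mean
    spectral energy moving toward higher frequencies.  A constant
    spectrogram yields zeros.
    """
    if spec.n_frames < 2:
        raise ValueError("need at least two frames to estimate flow")
    A = spec.A
    scale = A.max()
    if scale <= 0:
        return np.zeros(spec.n_frames - 1)
    A = A / scale
    out = np.empty(spec.n_frames - 1)
    for j in range(spec.n_frames - 1):
        out[j] = _horn_schunck_1d(A[:, j], A[:, j + 1], alpha, n_iter).mean()
    return out


def binarize_otsu(spec: Spectrogram, nbins: int = 256) -> BinarizedSpectrogram:
    """Global Otsu threshold maximizing between-class amplitude variance."""
    a = spec.A
    if np.ptp(a) == 0:
        raise ValueError("constant spectrogram cannot be binarized")
    thr = float(threshold_otsu(a, nbins=nbins))
    return BinarizedSpectrogram(a > thr, thr, spec.freqs, spec.frame_rate)


def pattern_net_signals(binarized: BinarizedSpectrogram) -> PatternSignal:
    """Net upward-minus-downward occurrence of each intensity-pair pattern.

    For pattern (s1, s2): the upward indicator at (f, t) is
    (A[f, t] == s1) and (A[f+1, t+1] == s2); the downward indicator uses
    (f-1, t+1).  Boundary frequency rows are excluded so both directions
    are defined everywhere, making the four net traces sum to zero exactly.
    """
    m = binarized.mask
    if m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("binarized grid too small for pattern analysis")
    a = m[1:-1, :-1]          # reference element (f, t), interior rows
    up = m[2:, 1:]            # (f+1, t+1)
    down = m[:-2, 1:]         # (f-1, t+1)
    net_grids: dict[str, np.ndarray] = {}
    traces: dict[str, np.ndarray] = {}
    for p, (s1, s2) in _PATTERN_SIGNS.items():
        v_up = (a == s1) & (up == s2)
        v_down = (a == s1) & (down == s2)
        net = v_up.astype(int) - v_down.astype(int)
        net_grids[p] = net
        traces[p] = net.mean(axis=0).astype(float)
    return PatternSignal(net_grids, traces, binarized.frame_rate)


def continuous_hrc_signals(spec: Spectrogram) -> PatternSignal:
    """Half-rectified Hassenstein-Reichardt correlator on amplitude derivatives.

    Temporal derivatives F[f, t] = A[f, t] - A[f, t-1] are split into
    positive and negative half-rectified parts; for each sign pair
    (s1, s2), the net signal is

        [s1 F(f, t)]+ [s2 F(f+1, t+1)]+  -  [s1 F(f, t+1)]+ [s2 F(f+1, t)]+

    averaged over frequency.  The sign pairs map onto the pattern names as
    (+,+) -> HH, (-,-) -> LL, (+,-) -> HL, (-,+) -> LH.
    """
    if spec.n_frames < 3:
        raise ValueError("need at least three frames for derivative correlators")
    F = np.diff(spec.A, axis=1)  # (n_freq, n_frames - 1)
    pos = np.clip(F, 0.0, None)
    neg = np.clip(-F, 0.0, None)
    half = {True: pos, False: neg}  # True: rectify the positive part
    net_grids: dict[str, np.ndarray] = {}
    traces: dict[str, np.ndarray] = {}
    for p, (s1, s2) in _PATTERN_SIGNS.items():
        r1, r2 = half[s1], half[s2]
        net = (r1[:-1, :-1] * r2[1:, 1:]) - (r1[:-1, 1:] * r2[1:, :-1])
        net_grids[p] = net
        traces[p] = net.mean(axis=0)
    return PatternSignal(net_grids, traces, spec.frame_rate)


def correlate_with_tone_change(signals: PatternSignal,
                               tone_change: np.ndarray) -> dict[str, float]:
    """Pearson r between each frequency-averaged net trace and tone change.

    Traces are trimmed to their common length from the start before
    correlating.
    """
    tone_change = np.asarray(tone_change, dtype=float)
    n = min(tone_change.size, min(t.size for t in signals.traces.values()))
    if n < 3:
        raise ValueError("need at least three common frames")
    out = {}
    for p, trace in signals.traces.items():
        out[p] = float(stats.pearsonr(trace[:n], tone_change[:n]).statistic)
    return out
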