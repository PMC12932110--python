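"""Synthetic fixtures standing in for speech corpora and human listeners.

``gen_chirp_waveform`` produces band-structured, frequency-sweeping audio
with a known tone-change sign and rate — a controllable stand-in for
speech snippets, so the full spectrogram/tone-change/pattern pipeline can
be exercised end to end without any corpus download.

``gen_observer_choices`` maps opponent-model outputs to binary
rising/falling judgements through a lapse-logistic link, replacing human
participants; ``fit_observer`` recovers the link parameters by maximum
likelihood, closing the loop for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .synthesis import DEFAULT_FS, Waveform

__all__ = [
    "ChirpSpec",
    "ObserverSpec",
    "gen_chirp_waveform",
    "gen_observer_choices",
    "observer_p_rising",
    "fit_observer",
]


@dataclass(frozen=True)
class ChirpSpec:
    """Frequency-sweeping multi-band stimulus with additive noise.

    Bands start at ``f_start`` and successive octaves above it, each a
    narrow cluster of ``band_width`` octaves, all sweeping together at
    ``sweep_rate`` octaves per second (rising or falling).  The narrow
    default clusters place their three partials a few hertz apart, so each
    band beats slowly — the amplitude texture that, like speech, feeds the
    correlation analyses.  ``noise_sd`` is the white-noise amplitude
    relative to unit band amplitude.  ``f_start = None`` centres the
    feasible start range so all bands stay within the 100-6400 Hz analysis
    window for the whole sweep.
    """

    direction: str = "rise"
    sweep_rate: float = 1.5      # octaves / s
    f_start: float | None = None
    duration: float = 1.5
    n_harmonic_bands: int = 3
    band_width: float = 0.02     # octaves
    noise_sd: float = 0.1
    seed: int = 0
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.direction not in ("rise", "fall"):
            raise ValueError("direction must be 'rise' or 'fall'")
        if self.sweep_rate <= 0 or self.duration <= 0:
            raise ValueError("sweep_rate and duration must be positive")
        if self.n_harmonic_bands < 1:
            raise ValueError("need at least one band")
        f = self.start_frequency  # validates the range
        assert f > 0

    @property
    def start_frequency(self) -> float:
        """Lowest band centre at t = 0 (auto-placed when f_start is None)."""
        total = self.sweep_rate * self.duration
        span = self.n_harmonic_bands - 1 + self.band_width
        lo = 100.0 * 2.0 ** (self.band_width / 2)
        hi = 6400.0 / 2.0 ** (span - self.band_width / 2 + total)
        if self.f_start is None:
            if hi <= lo:
                raise ValueError(
                    "bands cannot fit the 100-6400 Hz window over this sweep")
            f0 = float(np.sqrt(lo * hi))
            return f0 if self.direction == "rise" else f0 * 2.0 ** total
        sign = 1.0 if self.direction == "rise" else -1.0
        total_sweep = sign * total
        top = self.f_start * 2.0 ** (self.n_harmonic_bands - 1 + self.band_width / 2)
        bottom = self.f_start * 2.0 ** (-self.band_width / 2)
        for edge in (bottom, top):
            for t_end in (0.0, total_sweep):
                f = edge * 2.0 ** t_end
                if not 100.0 <= f <= 6400.0:
                    raise ValueError(
                        f"band edge sweeps to {f:.0f} Hz, outside the "
                        "100-6400 Hz analysis range")
        return self.f_start


def gen_chirp_waveform(spec: ChirpSpec) -> Waveform:
    """Render the swept multi-band chirp plus white noise, peak-normalized.

    Each band is realized as three sub-tones spread across ``band_width``
    octaves; the instantaneous frequency of a component starting at f0 is
    f0 * 2**(+-sweep_rate * t), integrated exactly for the phase.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.fs)
    t = np.arange(n) / spec.fs
    sign = 1.0 if spec.direction == "rise" else -1.0
    r = sign * spec.sweep_rate
    # phase of f0 * 2^(r t): 2 pi f0 (2^(r t) - 1) / (r ln 2)
    growth = (2.0 ** (r * t) - 1.0) / (r * np.log(2.0))
    w = np.zeros(n)
    offsets = np.linspace(-spec.band_width / 2, spec.band_width / 2, 3)
    f_start = spec.start_frequency
    for band in range(spec.n_harmonic_bands):
        for off in offsets:
            f0 = f_start * 2.0 ** (band + off)
            phase0 = rng.uniform(0, 2 * np.pi)
            w += np.sin(2.0 * np.pi * f0 * growth + phase0)
    if spec.noise_sd > 0:
        w += rng.normal(0.0, spec.noise_sd, size=n)
    peak = float(np.max(np.abs(w)))
    return Waveform(w / peak, spec.fs, norm_factor=peak)


@dataclass(frozen=True)
class ObserverSpec:
    """Lapse-logistic observer: P(rising | x) = lapse/2 + (1-lapse) * sigma(gain x + bias)."""

    gain: float = 1.0
    bias: float = 0.0
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


def observer_p_rising(x, spec: ObserverSpec) -> np.ndarray:
    """Probability of a 'rising' judgement for decision variables x."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("decision variables must be finite")
    return spec.lapse / 2.0 + (1.0 - spec.lapse) * expit(spec.gain * x + spec.bias)


def gen_observer_choices(opponent_means, spec: ObserverSpec) -> np.ndarray:
    """Sample binary rising (1) / falling (0) choices from the observer."""
    p = observer_p_rising(opponent_means, spec)
    rng = np.random.default_rng(spec.seed)
    return (rng.random(p.shape) < p).astype(int)


def fit_observer(x, choices, lapse: float = 0.0) -> ObserverSpec:
    """Maximum-likelihood fit of (gain, bias) at a fixed lapse rate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(choices, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and choices must have equal shape")

    def nll(theta):
        p = lapse / 2.0 + (1.0 - lapse) * expit(theta[0] * x + theta[1])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    return ObserverSpec(gain=float(res.x[0]), bias=float(res.x[1]), lapse=lapse)
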