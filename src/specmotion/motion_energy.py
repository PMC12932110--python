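"""Toy motion-energy unit on spectrogram rows, opponency and its symmetry.

The unit convolves two temporal filters with the envelopes of two adjacent
frequency channels and squares the summed output:

    r(t) = ((f1 * S1)(t) + (f2 * S2)(t))^2

with f1(t) = t^2 / tau^3 * exp(-t / tau) (peak at 2 tau) and f2 a copy of
f1 delayed by T and gated by a Heaviside step.  S1 is the upper and S2 the
lower of two adjacent frequency channels: delaying the lower channel's
signal aligns it with energy that subsequently arrives on the upper
channel, so the unit responds preferentially to intensity patterns
sweeping upward in frequency.  The opponent signal subtracts the
frequency-flipped unit:

    r_opp(t) = ((f1*S1) + (f2*S2))^2 - ((f2*S1) + (f1*S2))^2

For stimuli whose covariance is a delta at zero lag (amplitude beta) plus
deltas at +-(delta_f, delta_t) (amplitude alpha), opponent subtraction
removes the beta term, leaving a mean response proportional to alpha.  As a
consequence, inverting the correlation sign is equivalent to inverting the
stimulus direction:  <r_opp(-alpha, dt, df)> = <r_opp(alpha, dt, -df)>.
``symmetry_check`` verifies that identity numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import FrequencyGrid, PipSpec, build_pip_mask

__all__ = [
    "TemporalFilter",
    "UnitResponse",
    "TuningCurve",
    "CorrelatedEnsembleSpec",
    "eval_filters",
    "pip_trial_means",
    "ternary_opponent_means",
    "unit_response",
    "opponent_response",
    "tuning_sweep",
    "symmetry_check",
]

_DT = 1e-3  # convolution grid, seconds


@dataclass(frozen=True)
class TemporalFilter:
    """Gamma-shaped temporal filter: timescale tau and delay T (seconds)."""

    tau: float = 0.020
    T: float = 0.040

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.T < 0:
            raise ValueError("T must be nonnegative")


@dataclass
class UnitResponse:
    """Response trace r(t) and its time average."""

    trace: np.ndarray
    dt: float

    @property
    def mean_response(self) -> float:
        return float(self.trace.mean())


@dataclass
class TuningCurve:
    """Mean (opponent) response vs. a stimulus parameter, per condition."""

    param: str
    table: pd.DataFrame  # columns: value, condition, mean, se, n_trials
    opponent: bool

    def curve(self, condition: str) -> pd.DataFrame:
        return self.table[self.table.condition == condition].sort_values("value")


@dataclass(frozen=True)
class CorrelatedEnsembleSpec:
    """Two-channel correlated impulse ensemble.

    ``beta`` sets the per-channel event rate (events per second per
    channel); ``alpha`` sets the signed cross-channel correlation: each
    initiator event spawns a partner on the other channel at +delta_t with
    matching (alpha > 0) or inverted (alpha < 0) sign, with probability
    |alpha| / beta.  ``delta_f`` = +1 directs the correlation from the
    lower channel to the upper (upward), -1 the reverse.
    """

    alpha: float
    beta: float
    delta_t: float = 0.040
    delta_f: int = 1
    n_trials: int = 40
    duration: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if abs(self.alpha) > self.beta:
            raise ValueError("|alpha| must not exceed beta")
        if self.delta_f not in (-1, 1):
            raise ValueError("delta_f must be +-1")


def eval_filters(filt: TemporalFilter, t_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate f1 and its delayed, Heaviside-gated copy f2 on a time grid."""
    t = np.asarray(t_grid, dtype=float)
    if t.size and (t.min() < 0 or np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be nonnegative and increasing")
    tau, T = filt.tau, filt.T
    f1 = t ** 2 / tau ** 3 * np.exp(-t / tau)
    ts = t - T
    f2 = np.where(ts > 0, ts ** 2 / tau ** 3 * np.exp(-np.clip(ts, 0, None) / tau), 0.0)
    return f1, f2


def _filter_kernels(filt: TemporalFilter, dt: float = _DT) -> tuple[np.ndarray, np.ndarray]:
    # truncate at 10 tau past the delay; residual tail mass < 1e-3
    t = np.arange(0.0, filt.T + 10.0 * filt.tau, dt)
    return eval_filters(filt, t)


def _causal_conv(x: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    return np.convolve(x, kernel)[: x.size] * dt


def unit_response(S1: np.ndarray, S2: np.ndarray, filt: TemporalFilter,
                  dt: float = _DT) -> UnitResponse:
    """Single upward-selective unit: square of f1*S1 + f2*S2.

    S1 is the upper and S2 the lower adjacent frequency channel; the
    delayed filter on the lower channel gives upward selectivity.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError("S1 and S2 must have equal length")
    f1, f2 = _filter_kernels(filt, dt)
    out = _causal_conv(S1, f1, dt) + _causal_conv(S2, f2, dt)
    return UnitResponse(out ** 2, dt)


def opponent_response(S1: np.ndarray, S2: np.ndarray, filt: TemporalFilter,
                      dt: float = _DT) -> UnitResponse:
    """Opponent signal: upward-selective unit minus its frequency flip."""
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError("S1 and S2 must have equal length")
    f1, f2 = _filter_kernels(filt, dt)
    a1, a2 = _causal_conv(S1, f1, dt), _causal_conv(S2, f2, dt)
    b1, b2 = _causal_conv(S1, f2, dt), _causal_conv(S2, f1, dt)
    return UnitResponse((a1 + a2) ** 2 - (b1 + b2) ** 2, dt)


def _mask_mean_response(values: np.ndarray, filt: TemporalFilter, dt: float,
                        opponent: bool) -> float:
    """Mean (opponent) response over all adjacent channel pairs of a mask."""
    x = 2.0 * (values - 0.5)  # centred envelope on the +-1 scale
    burn = round((filt.T + 5 * filt.tau) / dt)
    fn = opponent_response if opponent else unit_response
    means = [fn(x[i + 1], x[i], filt, dt).trace[burn:].mean()
             for i in range(x.shape[0] - 1)]
    return float(np.mean(means))


def pip_trial_means(note: int, parity: int, delay: float, n_trials: int,
                    seed: int, opponent: bool = True,
                    filt: TemporalFilter | None = None,
                    base_rate: float = 4.0, duration: float = 5.0,
                    n_channels: int = 12, pip_duration: float = 20.0,
                    shuffle_channels: bool = False) -> np.ndarray:
    """Per-trial mean (opponent) responses to correlated-pip stimuli.

    Each trial draws a fresh pip mask (note = signed frequency displacement,
    parity = correlation sign, delay in ms) and averages the response over
    all adjacent channel pairs.  ``shuffle_channels`` permutes the channel
    order to destroy cross-channel correlations (an uncorrelated control
    with identical per-channel statistics).
    """
    filt = filt or TemporalFilter()
    grid = FrequencyGrid(f_min=200.0, steps_per_octave=15,
                         n_octaves=max(1, (n_channels - 1) // 15 + 1))
    rng = np.random.default_rng(seed)
    means = np.empty(n_trials)
    for k in range(n_trials):
        sub_seed = int(rng.integers(0, 2 ** 31))
        spec = PipSpec(base_rate=base_rate, pip_duration=pip_duration,
                       delay=delay, note=note, parity=parity)
        mask, _ = build_pip_mask(grid, spec, duration, sub_seed)
        v = mask.values[:n_channels]
        if shuffle_channels:
            v = v[np.random.default_rng(sub_seed + 1).permutation(v.shape[0])]
        means[k] = _mask_mean_response(v, filt, mask.sample_period, opponent)
    return means


def ternary_opponent_means(Q: int, d: int, coherence: float, n_trials: int,
                           seed: int, filt: TemporalFilter | None = None,
                           n_channels: int = 30, n_frames: int = 12,
                           frame_duration: float = 1.0 / 6.0) -> np.ndarray:
    """Per-trial mean opponent responses to ternary correlated-noise stimuli.

    Trials draw fresh base masks, impose the (d, Q) correlation, degrade to
    the requested coherence, expand to a 1-ms envelope grid and average the
    opponent response over adjacent channel pairs.
    """
    from .masks import CorrelationSpec, build_ternary_mask, degrade_coherence
    from .masks import sample_binary_base

    filt = filt or TemporalFilter()
    spec = CorrelationSpec(d=d, Q=Q, coherence=coherence)
    rng = np.random.default_rng(seed)
    rep = round(frame_duration * 1000.0)
    means = np.empty(n_trials)
    for k in range(n_trials):
        s = int(rng.integers(0, 2 ** 31))
        base = sample_binary_base(n_channels + abs(d), n_frames + 1, s,
                                  frame_duration)
        mask = build_ternary_mask(base, spec)
        if coherence < 1.0:
            mask = degrade_coherence(mask, coherence, s + 1)
        env = np.repeat(mask.values, rep, axis=1)
        means[k] = _mask_mean_response(env, filt, 1e-3, opponent=True)
    return means


def tuning_sweep(param: str, values, conditions=None, n_trials: int = 10,
                 seed: int = 0, opponent: bool = False,
                 filt: TemporalFilter | None = None,
                 base_rate: float = 4.0, duration: float = 5.0,
                 n_channels: int = 12, pip_duration: float = 20.0) -> TuningCurve:
    """Sweep the model over correlated-pip stimuli.

    ``param`` is ``"delay"`` (ms) or ``"note"`` (grid steps); conditions are
    drawn from ``{"up+", "up-", "down+", "down-", "random"}`` (direction of
    the imposed correlation x parity; ``random`` shuffles channel order to
    destroy all cross-channel correlation while preserving per-channel
    statistics).  Stimuli are generated per trial from the pip-mask
    generator; the mean (opponent) response is averaged over all adjacent
    channel pairs and reported with its standard error over trials.
    """
    if param not in ("delay", "note"):
        raise ValueError("param must be 'delay' or 'note'")
    values = list(values)
    if not values:
        raise ValueError("values must be nonempty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if conditions is None:
        conditions = ["up+", "up-", "down+", "down-"]
    cond_map = {"up+": (1, 1), "up-": (1, -1), "down+": (-1, 1),
                "down-": (-1, -1), "random": (1, 1)}
    for c in conditions:
        if c not in cond_map:
            raise ValueError(f"unknown condition {c!r}")
    filt = filt or TemporalFilter()
    rng = np.random.default_rng(seed)
    rows = []
    for value in values:
        for cond in conditions:
            note_sign, parity = cond_map[cond]
            delay = value if param == "delay" else 40.0
            note = note_sign * (1 if param == "delay" else int(value))
            trial_means = pip_trial_means(
                note, parity, delay, n_trials, int(rng.integers(0, 2 ** 31)),
                opponent=opponent, filt=filt, base_rate=base_rate,
                duration=duration, n_channels=n_channels,
                pip_duration=pip_duration,
                shuffle_channels=(cond == "random"))
            rows.append({
                "value": value, "condition": cond,
                "mean": float(trial_means.mean()),
                "se": float(trial_means.std(ddof=1) / np.sqrt(n_trials))
                if n_trials > 1 else np.nan,
                "n_trials": n_trials,
            })
    return TuningCurve(param, pd.DataFrame(rows), opponent)


def gen_pair_ensemble(spec: CorrelatedEnsembleSpec, rng: np.random.Generator,
                      dt: float = _DT) -> tuple[np.ndarray, np.ndarray]:
    """One realization of the two-channel correlated impulse ensemble.

    Returns centred impulse traces (S_low, S_high).  Impulses have unit
    amplitude and +-1 sign; paired partners appear on the other channel at
    +delta_t.  Unpaired events on the partner channel keep the two
    channel rates equal, so the single-channel statistics are independent
    of alpha.
    """
    n_t = round(spec.duration / dt)
    lag = round(spec.delta_t / dt)
    n_ev = rng.poisson(spec.beta * spec.duration)
    t0 = rng.integers(0, max(1, n_t - lag), size=n_ev)
    s0 = rng.choice([-1.0, 1.0], size=n_ev)
    paired = rng.random(n_ev) < (abs(spec.alpha) / spec.beta if spec.alpha else 0.0)
    pair_sign = 1.0 if spec.alpha >= 0 else -1.0

    src = np.zeros(n_t)
    dst = np.zeros(n_t)
    np.add.at(src, t0, s0)
    np.add.at(dst, t0[paired] + lag, pair_sign * s0[paired])
    # independent events keeping the partner-channel rate at beta
    n_free = int((~paired).sum())
    tf = rng.integers(0, n_t, size=n_free)
    np.add.at(dst, tf, rng.choice([-1.0, 1.0], size=n_free))

    if spec.delta_f == 1:
        return src, dst  # correlation directed low -> high: upward
    return dst, src


def _ensemble_mean_opp(spec: CorrelatedEnsembleSpec, filt: TemporalFilter,
                       rng: np.random.Generator, opponent: bool = True,
                       dt: float = _DT) -> tuple[float, float]:
    """Mean and SE over trials of the (opponent) response to an ensemble."""
    burn = round((filt.T + 5 * filt.tau) / dt)
    fn = opponent_response if opponent else unit_response
    means = np.empty(spec.n_trials)
    for k in range(spec.n_trials):
        s_low, s_high = gen_pair_ensemble(spec, rng, dt)
        means[k] = fn(s_high, s_low, filt, dt).trace[burn:].mean()
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(spec.n_trials))


def symmetry_check(spec: CorrelatedEnsembleSpec,
                   filt: TemporalFilter | None = None,
                   delays=(0.020, 0.040, 0.060, 0.080, 0.100),
                   opponent: bool = True) -> float:
    """Max discrepancy (in pooled-SE units) between correlation inversion
    and direction inversion across a delay sweep.

    Compares <r_opp(-alpha, dt, delta_f)> with <r_opp(alpha, dt, -delta_f)>
    at each delay; for an opponent signal the two are equal in expectation,
    so the statistic should stay within ~3.  Run with ``opponent=False`` the
    same statistic exposes the single (non-opponent) unit's asymmetry.
    """
    from dataclasses import replace

    filt = filt or TemporalFilter()
    rng = np.random.default_rng(spec.seed)
    worst = 0.0
    for delta_t in delays:
        a = replace(spec, alpha=-spec.alpha, delta_t=delta_t)
        b = replace(spec, delta_f=-spec.delta_f, delta_t=delta_t)
        m_a, se_a = _ensemble_mean_opp(a, filt, rng, opponent)
        m_b, se_b = _ensemble_mean_opp(b, filt, rng, opponent)
        z = abs(m_a - m_b) / np.hypot(se_a, se_b)
        worst = max(worst, float(z))
    return worst
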