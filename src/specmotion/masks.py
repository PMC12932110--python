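"""Discrete envelope masks defining spectrotemporal-correlation stimuli.

All stimuli in this package are built from coarse (frame-based) or fine
(millisecond-based) masks over a log-spaced frequency grid.  A *ternary
correlated noise* mask is a binary random field added to a frequency- and
time-shifted copy of itself, which imposes a single pairwise intensity
correlation at a chosen spectrotemporal offset; the sign of the copy (the
parity Q) makes that correlation positive or negative.  *Correlated pip*
masks place sparse high/low intensity pips on a mid-level background, with
partner pips at a chosen frequency and time offset.  *Triplet* masks carry
a third-order glider correlation with vanishing pairwise structure, and
*sweep* masks are deterministic rising/falling tone lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FrequencyGrid",
    "CoarseMask",
    "FineMask",
    "CorrelationSpec",
    "PipSpec",
    "PipStats",
    "LEVELS_PM_HALF",
    "LEVELS_TERNARY",
    "LEVELS_BINARY01",
    "sample_binary_base",
    "build_ternary_mask",
    "degrade_coherence",
    "split_binaural",
    "build_pip_mask",
    "build_triplet_mask",
    "build_sweep_mask",
    "save_mask_tsv",
    "load_mask_tsv",
]

# Level-set tags for CoarseMask / FineMask values.
LEVELS_PM_HALF = "pm_half"      # {-1/2, +1/2}: centred Bernoulli base
LEVELS_TERNARY = "ternary"      # {0, 0.5, 1}: correlated-noise and pip masks
LEVELS_BINARY01 = "binary01"    # {0, 1}: binaural / triplet / sweep masks

_LEVEL_VALUES = {
    LEVELS_PM_HALF: (-0.5, 0.5),
    LEVELS_TERNARY: (0.0, 0.5, 1.0),
    LEVELS_BINARY01: (0.0, 1.0),
}


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-spaced carrier comb: ``carriers[i] = f_min * 2**(i / steps_per_octave)``.

    Defaults give the 15-steps-per-octave comb from 200 Hz to 6400 Hz used
    by the correlated-noise stimuli (76 carriers, the top one at exactly
    6400 Hz).
    """

    f_min: float = 200.0
    steps_per_octave: int = 15
    n_octaves: int = 5

    def __post_init__(self) -> None:
        if self.f_min <= 0:
            raise ValueError("f_min must be positive")
        if self.steps_per_octave < 1 or self.n_octaves < 1:
            raise ValueError("steps_per_octave and n_octaves must be >= 1")

    @property
    def carriers(self) -> np.ndarray:
        n = self.steps_per_octave * self.n_octaves + 1
        return self.f_min * 2.0 ** (np.arange(n) / self.steps_per_octave)

    @property
    def n_carriers(self) -> int:
        return self.steps_per_octave * self.n_octaves + 1


def _check_levels(values: np.ndarray, level_set: str) -> None:
    allowed = _LEVEL_VALUES.get(level_set)
    if allowed is None:
        raise ValueError(f"unknown level_set {level_set!r}")
    if not np.isin(values, allowed).all():
        raise ValueError(f"mask values outside level set {level_set!r}")


@dataclass
class CoarseMask:
    """Frame-based envelope mask: rows are frequency channels, columns frames."""

    values: np.ndarray
    frame_duration: float
    level_set: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        _check_levels(self.values, self.level_set)

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class FineMask:
    """Millisecond-resolution envelope mask with levels {0, 0.5, 1}.

    0.5 is the background level; pips appear as excursions to 1 (high) or
    0 (low).
    """

    values: np.ndarray
    sample_period: float  # seconds per column (1 ms default)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        _check_levels(self.values, LEVELS_TERNARY)

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CorrelationSpec:
    """Pairwise-correlation parameters: displacement d (grid steps, one frame
    later), parity Q = +-1, and coherence (fraction of mask elements retaining
    the imposed correlation)."""

    d: int = 1
    Q: int = 1
    coherence: float = 1.0

    def __post_init__(self) -> None:
        if self.Q not in (-1, 1):
            raise ValueError("Q must be +1 or -1")
        if self.d == 0:
            raise ValueError("d must be nonzero")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")


@dataclass(frozen=True)
class PipSpec:
    """Correlated-pip parameters.

    base_rate is the rate of *initial* Poisson pip events per frequency
    channel per second; pairing doubles the realized rate.  ``parity`` is
    +-1 for sign-correlated pairs, or one of ``"HH" | "LL" | "HL" | "LH"``
    for the intensity-combination stimuli in which only two thirds of pips
    are in correlated pairs.
    """

    base_rate: float = 4.0
    pip_duration: float = 50.0        # ms
    delay: float = 40.0               # ms, onset-to-onset of paired events
    note: int = 1                     # frequency displacement in grid steps
    parity: int | str = 1
    envelope_resolution: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        if self.pip_duration <= 0 or self.envelope_resolution <= 0:
            raise ValueError("pip_duration and envelope_resolution must be positive")
        if isinstance(self.parity, str):
            if self.parity not in ("HH", "LL", "HL", "LH"):
                raise ValueError("combination kind must be HH, LL, HL or LH")
        elif self.parity not in (-1, 1):
            raise ValueError("parity must be +-1 or a combination kind")

    @property
    def is_combination(self) -> bool:
        return isinstance(self.parity, str)


@dataclass
class PipStats:
    """Bookkeeping for a generated pip mask."""

    n_initial: int = 0
    n_partners: int = 0
    n_fillers: int = 0
    n_dropped: int = 0      # partner events falling off the frequency grid
    n_collisions: int = 0   # pips overwriting an earlier overlapping pip
    channel_seconds: float = 0.0

    @property
    def n_events(self) -> int:
        return self.n_initial + self.n_partners + self.n_fillers

    @property
    def realized_rate(self) -> float:
        """Realized pips per channel per second."""
        return self.n_events / self.channel_seconds

    @property
    def paired_fraction(self) -> float:
        """Fraction of all placed pips that belong to a correlated pair."""
        return (self.n_initial + self.n_partners - self.n_dropped) / self.n_events


def sample_binary_base(n_freq: int, n_frames: int, seed: int,
                       frame_duration: float = 1.0 / 6.0) -> CoarseMask:
    """Sample the binary base mask B: i.i.d. Bernoulli(0.5) centred to +-1/2."""
    if n_freq < 1 or n_frames < 1:
        raise ValueError("n_freq and n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(n_freq, n_frames)).astype(float) - 0.5
    return CoarseMask(values, frame_duration, LEVELS_PM_HALF, seed=seed)


def build_ternary_mask(base: CoarseMask, spec: CorrelationSpec) -> CoarseMask:
    """Ternary correlated-noise mask M[i, j] = B[i, j] + Q * B[i+d, j+1].

    The base is cropped by |d| rows and one frame so every output element is
    defined without wraparound; the {-1, 0, 1} sum is recentred to
    {0, 0.5, 1}.  The centred mask (on its +-1 scale) has autocovariance
    1/2 at zero lag and Q/4 at offsets +-(d, 1).
    """
    if base.level_set != LEVELS_PM_HALF:
        raise ValueError("base mask must have the +-1/2 level set")
    d = spec.d
    if base.n_freq < abs(d) + 1 or base.n_frames < 2:
        raise ValueError("base mask too small for the requested displacement")
    B = base.values
    lo = max(0, -d)
    n_out = base.n_freq - abs(d)
    rows = slice(lo, lo + n_out)
    shifted = slice(lo + d, lo + d + n_out)
    M = B[rows, :-1] + spec.Q * B[shifted, 1:]
    return CoarseMask((M + 1.0) / 2.0, base.frame_duration, LEVELS_TERNARY,
                      seed=base.seed)


def degrade_coherence(mask: CoarseMask, coherence: float, seed: int) -> CoarseMask:
    """Replace a fraction (1 - coherence) of elements with random ternary draws.

    Replacement positions are chosen uniformly without replacement; the
    replacement values are i.i.d. from (0, 0.5, 1) with probabilities
    (0.25, 0.5, 0.25), matching the marginal distribution of the intact mask.
    """
    if mask.level_set != LEVELS_TERNARY:
        raise ValueError("coherence degradation applies to ternary masks")
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    values = mask.values.copy()
    n_replace = round((1.0 - coherence) * values.size)
    if n_replace:
        rng = np.random.default_rng(seed)
        idx = rng.choice(values.size, size=n_replace, replace=False)
        values.flat[idx] = rng.choice([0.0, 0.5, 1.0], size=n_replace,
                                      p=[0.25, 0.5, 0.25])
    return CoarseMask(values, mask.frame_duration, LEVELS_TERNARY, seed=seed)


def split_binaural(base: CoarseMask, spec: CorrelationSpec) -> tuple[CoarseMask, CoarseMask]:
    """Split the correlation across two ears.

    Ear A plays B[i, j], ear B plays Q * B[i+d, j+1]; both are recentred to
    {0, 1}.  Neither ear alone carries any pairwise correlation; only the
    cross-ear correlation is nonzero, with sign Q.  Because ear B already
    carries the shifted copy, the correlated offset runs from ear B toward
    ear A: cov(earB[i, j], earA[i+d, j+1]) = Q/4 (an element heard in ear B
    reappears one frame later, d frequency steps up, in ear A).
    """
    if base.level_set != LEVELS_PM_HALF:
        raise ValueError("base mask must have the +-1/2 level set")
    d = spec.d
    if base.n_freq < abs(d) + 1 or base.n_frames < 2:
        raise ValueError("base mask too small for the requested displacement")
    B = base.values
    lo = max(0, -d)
    n_out = base.n_freq - abs(d)
    ear_a = B[lo:lo + n_out, :-1] + 0.5
    ear_b = spec.Q * B[lo + d:lo + d + n_out, 1:] + 0.5
    fd = base.frame_duration
    return (CoarseMask(ear_a, fd, LEVELS_BINARY01, seed=base.seed),
            CoarseMask(ear_b, fd, LEVELS_BINARY01, seed=base.seed))


def _place_pips(trace: np.ndarray, channel: np.ndarray, onset: np.ndarray,
                sign: np.ndarray, dur: int) -> int:
    """Write boxcar pips onto the event trace; later onsets overwrite.

    Returns the number of collisions (pips overlapping an earlier pip on the
    same channel).
    """
    order = np.argsort(onset, kind="stable")
    collisions = 0
    n_t = trace.shape[1]
    for ch, t0, s in zip(channel[order], onset[order], sign[order]):
        t1 = min(t0 + dur, n_t)
        if np.any(trace[ch, t0:t1]):
            collisions += 1
        trace[ch, t0:t1] = s
    return collisions


def build_pip_mask(grid: FrequencyGrid, spec: PipSpec, duration: float,
                   seed: int) -> tuple[FineMask, PipStats]:
    """Generate a correlated-pip envelope mask.

    Initial delta-function pip events are placed as a Poisson process at
    ``base_rate`` per channel-second with equiprobable +-1 sign.  In parity
    mode every initial event spawns a partner at (+note, +delay) whose sign
    is parity * sign, doubling the overall rate.  For the intensity
    combination kinds (HH/LL/HL/LH) two thirds of all pips form correlated
    pairs of the requested kind and the remaining third are unpaired filler
    pips (HH -> low fillers, LL -> high fillers, HL/LH -> half each).
    Partners falling off the frequency grid are dropped and counted.  Event
    traces are convolved with a boxcar of the pip duration; the returned
    mask has levels {0, 0.5, 1} on a 0.5 background.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if (spec.delay + spec.pip_duration) / 1000.0 >= duration:
        raise ValueError("delay + pip_duration must be shorter than the stimulus")
    rng = np.random.default_rng(seed)
    dt = spec.envelope_resolution / 1000.0
    n_t = round(duration / dt)
    n_f = grid.n_carriers
    dur = max(1, round(spec.pip_duration / spec.envelope_resolution))
    delay = round(spec.delay / spec.envelope_resolution)

    stats = PipStats(channel_seconds=n_f * duration)

    # Initial Poisson events. In combination mode the initiator rate is one
    # third of base_rate (pairs provide 2/3 of pips, fillers the rest at an
    # equal per-pip rate to the initiators).
    init_rate = spec.base_rate / 3.0 if spec.is_combination else spec.base_rate
    n_init = rng.poisson(init_rate * duration * n_f)
    ch = rng.integers(0, n_f, size=n_init)
    t0 = rng.integers(0, n_t, size=n_init)

    if spec.is_combination:
        kind = spec.parity
        s_init = np.full(n_init, 1.0 if kind[0] == "H" else -1.0)
        s_part = np.full(n_init, 1.0 if kind[1] == "H" else -1.0)
    else:
        s_init = rng.choice([-1.0, 1.0], size=n_init)
        s_part = spec.parity * s_init
    stats.n_initial = n_init

    pch = ch + spec.note
    pt = t0 + delay
    keep = (pch >= 0) & (pch < n_f) & (pt < n_t)
    stats.n_dropped = int((~keep).sum())
    stats.n_partners = int(keep.sum())

    channels = [ch, pch[keep]]
    onsets = [t0, pt[keep]]
    signs = [s_init, s_part[keep]]

    if spec.is_combination:
        # Unpaired fillers at half the initiator count in expectation
        # (1/3 of all pips when pairing is complete).
        n_fill = rng.poisson(init_rate * duration * n_f)
        fch = rng.integers(0, n_f, size=n_fill)
        ft = rng.integers(0, n_t, size=n_fill)
        kind = spec.parity
        if kind == "HH":
            fs = np.full(n_fill, -1.0)
        elif kind == "LL":
            fs = np.full(n_fill, 1.0)
        else:
            fs = rng.choice([-1.0, 1.0], size=n_fill)
        stats.n_fillers = n_fill
        channels.append(fch)
        onsets.append(ft)
        signs.append(fs)

    trace = np.zeros((n_f, n_t))
    stats.n_collisions = _place_pips(
        trace, np.concatenate(channels), np.concatenate(onsets),
        np.concatenate(signs), dur)
    return FineMask(0.5 + 0.5 * trace, dt, seed=seed), stats


def save_mask_tsv(path, mask: CoarseMask) -> None:
    """Write a coarse mask as TSV (rows = frequency channels) with a
    metadata header; round-trips exactly through load_mask_tsv."""
    with open(path, "w") as fh:
        fh.write(f"# frame_duration\t{mask.frame_duration!r}\n")
        fh.write(f"# level_set\t{mask.level_set}\n")
        fh.write(f"# seed\t{'' if mask.seed is None else mask.seed}\n")
        for row in mask.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_mask_tsv(path) -> CoarseMask:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                meta[key] = val
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    if "frame_duration" not in meta or "level_set" not in meta:
        raise ValueError(f"not a mask TSV file: {path}")
    seed = int(meta["seed"]) if meta.get("seed") else None
    return CoarseMask(np.array(rows), float(meta["frame_duration"]),
                      meta["level_set"], seed=seed)


_GLIDERS = {
    # (mode, orientation) -> offsets of the two parent elements relative to
    # the new element at (i, j). Converging: two frequency-adjacent parents
    # one frame earlier; diverging: one parent one frame earlier plus one
    # frequency-adjacent parent in the same frame.
    ("converging", "up"): ((-1, -1), (0, -1)),
    ("converging", "down"): ((1, -1), (0, -1)),
    ("diverging", "up"): ((-1, -1), (-1, 0)),
    ("diverging", "down"): ((1, -1), (1, 0)),
}


def build_triplet_mask(n_freq: int, n_frames: int, parity: int,
                       orientation: Literal["up", "down"],
                       mode: Literal["converging", "diverging"],
                       seed: int, frame_duration: float = 1.0 / 6.0) -> CoarseMask:
    """Binary mask carrying a pure third-order (glider) correlation.

    Boundary elements are i.i.d. Bernoulli; every interior element is set so
    that the product of the three centred (+-1) elements in the glider equals
    ``parity``.  All pairwise correlations vanish in expectation.
    """
    if n_freq < 2 or n_frames < 2:
        raise ValueError("n_freq and n_frames must be >= 2")
    if parity not in (-1, 1):
        raise ValueError("parity must be +-1")
    try:
        (df1, dj1), (df2, dj2) = _GLIDERS[(mode, orientation)]
    except KeyError:
        raise ValueError(f"unknown glider {mode!r}/{orientation!r}") from None
    rng = np.random.default_rng(seed)
    x = rng.choice([-1.0, 1.0], size=(n_freq, n_frames))
    freq_range = range(n_freq) if orientation == "up" else range(n_freq - 1, -1, -1)
    for j in range(1, n_frames):
        for i in freq_range:
            i1, j1 = i + df1, j + dj1
            i2, j2 = i + df2, j + dj2
            if 0 <= i1 < n_freq and 0 <= i2 < n_freq:
                x[i, j] = parity * x[i1, j1] * x[i2, j2]
    return CoarseMask((x + 1.0) / 2.0, frame_duration, LEVELS_BINARY01, seed=seed)


def build_sweep_mask(n_freq: int, n_frames: int,
                     direction: Literal["rise", "fall", "sum"],
                     frame_duration: float = 1.0 / 6.0) -> CoarseMask:
    """Deterministic tone-sweep mask: an ascending or descending line of
    time-frequency elements, or their sum.

    For ``sum`` the grid must be such that the ascending and descending
    lines never occupy the same element (no frame where the two tones play
    the same frequency).
    """
    if n_freq < n_frames:
        raise ValueError("sweep line does not fit: need n_freq >= n_frames")
    rise = np.zeros((n_freq, n_frames))
    rise[np.arange(n_frames), np.arange(n_frames)] = 1.0
    if direction == "rise":
        values = rise
    elif direction == "fall":
        values = rise[::-1]
    elif direction == "sum":
        both = rise + rise[::-1]
        if both.max() > 1.0:
            raise ValueError(
                "ascending and descending lines coincide; choose a grid where "
                "n_freq - 1 - 2*j is never zero (e.g. even n_freq)")
        values = both
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return CoarseMask(values, frame_duration, LEVELS_BINARY01)
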