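"""Mask correlation structure and the tracking-heuristic pattern analysis.

The ternary correlated-noise mask M = B + Q * B_shifted (on its centred
+-1 scale) has the discrete autocovariance

    C(m, n) = 1/2 * delta(m,0) delta(n,0)
            + Q/4 * (delta(m,d) delta(n,1) + delta(m,-d) delta(n,-1))

i.e. the full variance at zero lag plus a single signed pairwise
correlation at the imposed spectrotemporal offset.  ``analytic_mask_autocorr``
returns this closed form and ``empirical_mask_autocorr`` its sample twin.

``pattern_occurrence`` implements the tracking-heuristic analysis: counting
how often high-high, low-low, high-low and low-high intensity pairs occur
at neighbouring frequencies and a fixed temporal offset, in the direction
of the imposed correlation ("with") and against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import (LEVELS_TERNARY, CoarseMask, CorrelationSpec, FineMask)

__all__ = [
    "CorrelationMap",
    "PatternCounts",
    "PATTERNS",
    "analytic_mask_autocorr",
    "empirical_mask_autocorr",
    "pattern_occurrence",
]

PATTERNS = ("HH", "LL", "HL", "LH")


@dataclass
class CorrelationMap:
    """Centred covariance over offsets (m frequency steps, n frames).

    ``values[max_m + m, max_n + n]`` holds C(m, n); the map satisfies
    C(m, n) = C(-m, -n).
    """

    values: np.ndarray
    max_m: int
    max_n: int

    def at(self, m: int, n: int) -> float:
        if abs(m) > self.max_m or abs(n) > self.max_n:
            raise ValueError(f"offset ({m}, {n}) outside the computed range")
        return float(self.values[self.max_m + m, self.max_n + n])


@dataclass
class PatternCounts:
    """Occurrence fractions of the four intensity-pair patterns.

    ``occurrence[pattern][direction]`` is the fraction of classified
    positions, over all evaluated (channel, time) positions, where that
    pattern occurred in the given direction; ``net[pattern]`` is the
    "with" fraction minus the "against" fraction.
    """

    occurrence: dict[str, dict[str, float]]
    net: dict[str, float]
    n_positions: int
    unclassified: dict[str, float]  # background-containing fraction per direction

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pattern": p, "direction": direction,
             "occurrence": self.occurrence[p][direction], "net": self.net[p]}
            for p in PATTERNS for direction in ("with", "against")
        ]
        return pd.DataFrame(rows)


def analytic_mask_autocorr(spec: CorrelationSpec, max_m: int = 3,
                           max_n: int = 3) -> CorrelationMap:
    """Closed-form autocovariance of the ternary mask on the +-1 scale."""
    values = np.zeros((2 * max_m + 1, 2 * max_n + 1))
    values[max_m, max_n] = 0.5
    if abs(spec.d) <= max_m and max_n >= 1:
        values[max_m + spec.d, max_n + 1] = spec.Q / 4.0
        values[max_m - spec.d, max_n - 1] = spec.Q / 4.0
    return CorrelationMap(values, max_m, max_n)


def empirical_mask_autocorr(mask: CoarseMask, max_m: int = 3,
                            max_n: int = 3) -> CorrelationMap:
    """Sample autocovariance of a mask at every offset up to (max_m, max_n).

    Uses only fully overlapping elements (no wraparound).  Ternary
    {0, 0.5, 1} masks are centred and rescaled by 2 so the result is on the
    same +-1 scale as the closed form; other level sets are only centred.
    """
    v = np.asarray(mask.values, dtype=float)
    if v.shape[0] <= max_m or v.shape[1] <= max_n:
        raise ValueError("offset range exceeds mask dimensions")
    x = v - v.mean()
    if mask.level_set == LEVELS_TERNARY:
        x = 2.0 * x
    values = np.zeros((2 * max_m + 1, 2 * max_n + 1))
    for m in range(-max_m, max_m + 1):
        for n in range(0, max_n + 1):
            if m < 0 and n == 0:
                continue
            a = x[max(0, -m):x.shape[0] - max(0, m),
                  max(0, -n):x.shape[1] - max(0, n)]
            b = x[max(0, m):x.shape[0] - max(0, -m),
                  max(0, n):x.shape[1] - max(0, -n)]
            c = float((a * b).mean())
            values[max_m + m, max_n + n] = c
            values[max_m - m, max_n - n] = c
    return CorrelationMap(values, max_m, max_n)


def cross_covariance(a: CoarseMask, b: CoarseMask, m: int, n: int) -> float:
    """Centred cross-covariance cov(a[i, j], b[i+m, j+n]) without wraparound."""
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("masks must share a shape")
    xa = va - va.mean()
    xb = vb - vb.mean()
    sa = xa[max(0, -m):va.shape[0] - max(0, m),
            max(0, -n):va.shape[1] - max(0, n)]
    sb = xb[max(0, m):vb.shape[0] - max(0, -m),
            max(0, n):vb.shape[1] - max(0, -n)]
    return float((sa * sb).mean())


def _to_millisecond_grid(env: CoarseMask | FineMask) -> tuple[np.ndarray, float]:
    """Envelope values on a 1-ms grid (zero-order hold for coarse masks)."""
    if isinstance(env, FineMask):
        return np.asarray(env.values, dtype=float), env.sample_period * 1000.0
    rep = max(1, round(env.frame_duration * 1000.0))
    return np.repeat(np.asarray(env.values, dtype=float), rep, axis=1), 1.0


def pattern_occurrence(env: FineMask | CoarseMask, delay_ms: float = 40.0,
                       d: int = 1) -> PatternCounts:
    """Count high/low intensity-pair patterns at a spectrotemporal offset.

    For every channel f and time step t (1-ms resolution), the pair
    (value(f, t), value(f + d, t + delay)) is classified as HH, LL, HL or
    LH, where high = 1 and low = 0; pairs containing the 0.5 background are
    left unclassified.  The "with" direction uses +d, "against" uses -d.
    The net occurrence of a pattern is its with-fraction minus its
    against-fraction.
    """
    values, step_ms = _to_millisecond_grid(env)
    lag = delay_ms / step_ms
    if abs(lag - round(lag)) > 1e-9:
        raise ValueError("delay must be a multiple of the envelope resolution")
    lag = round(lag)
    if values.shape[0] <= abs(d) or values.shape[1] <= lag:
        raise ValueError("envelope too small for the requested offset")

    high = values >= 0.75
    low = values <= 0.25

    occurrence: dict[str, dict[str, float]] = {p: {} for p in PATTERNS}
    unclassified: dict[str, float] = {}
    n_positions = 0
    for direction, dd in (("with", d), ("against", -d)):
        a_rows = slice(max(0, -dd), values.shape[0] - max(0, dd))
        b_rows = slice(max(0, dd), values.shape[0] - max(0, -dd))
        h1, l1 = high[a_rows, :values.shape[1] - lag], low[a_rows, :values.shape[1] - lag]
        h2, l2 = high[b_rows, lag:], low[b_rows, lag:]
        n = h1.size
        n_positions = n
        counts = {
            "HH": int((h1 & h2).sum()),
            "LL": int((l1 & l2).sum()),
            "HL": int((h1 & l2).sum()),
            "LH": int((l1 & h2).sum()),
        }
        for p in PATTERNS:
            occurrence[p][direction] = counts[p] / n
        unclassified[direction] = 1.0 - sum(counts.values()) / n
    net = {p: occurrence[p]["with"] - occurrence[p]["against"] for p in PATTERNS}
    return PatternCounts(occurrence, net, n_positions, unclassified)
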