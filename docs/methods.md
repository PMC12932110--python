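# Methods

`specmotion` implements the computational toolkit for studying how
rising/falling pitch can be signalled by local spectrotemporal intensity
correlations: generators for correlated-noise auditory stimuli, a toy
motion-energy/opponency model, the tracking-heuristic counting analysis,
and a spectrogram correlation pipeline for speech-like sounds. This note
records the models, the parameter choices, and the places where the design
was genuinely open.

## Stimulus construction

All stimuli are sums of sinusoidal carriers on a log-spaced comb
(`FrequencyGrid`, default 15 steps/octave from 200 Hz to 6400 Hz, 76
carriers), each multiplied by a slow amplitude envelope derived from a
discrete mask:

    w(t) = sum_i theta_i m_i(t) sin(2 pi f_i t)

sampled at 20 kHz. The weights theta_i are equal-loudness corrections from
the ISO 226 contour at 60 phon (the published 29-point parameter table,
interpolated in log-frequency and normalized to 1 at 1 kHz); they roughly
equalize the salience of the carriers and are not otherwise critical.

**Ternary correlated noise.** A binary Bernoulli(0.5) mask B (values
+-1/2) on a grid of frequency steps x 1/6-s frames is added to a copy of
itself displaced by d frequency steps and one frame, with sign Q:
M = B + Q B_shifted, recentred to {0, 0.5, 1}. On its centred +-1 scale
the mask's discrete autocovariance is exactly

    C(m, n) = 1/2 d(m,0) d(n,0) + Q/4 (d(m,d) d(n,1) + d(m,-d) d(n,-1))

a single signed pairwise correlation at the chosen spectrotemporal offset.
The base mask is generated one row and one frame larger than the output
and cropped, so no wraparound (and no spurious long-range correlation) is
introduced. Coherence is degraded by replacing a deterministic
round((1-C) N) element subset (uniform, without replacement) with i.i.d.
draws from (0, 0.5, 1) at probabilities (0.25, 0.5, 0.25) — the marginal
distribution of the intact mask — so only the correlation, not the level
statistics, changes. The covariance at the imposed offset then scales as
the probability that both members of a pair survive, ~C^2.

**Binaural masks.** The same construction split across ears: ear A plays
B, ear B plays Q B_shifted, each recentred to {0, 1}. Within either ear
the mask is pure Bernoulli noise (no correlation at any offset); the
imposed correlation exists only across ears. Because ear B carries the
already-shifted copy, the correlated cross-ear offset runs from ear B
toward ear A (cov(earB[i,j], earA[i+d,j+1]) = Q/4).

**Correlated pips.** Sparse +-1 delta events on a 0.5 background at 1-ms
resolution: initial events Poisson at 4 per channel-second with
equiprobable sign; each spawns a partner at (+note, +delay) with sign
parity x sign, doubling the rate to 8. For the intensity-combination
stimuli (HH/LL/HL/LH) initiator and filler rates are each one third of the
nominal 6 per channel-second, so two thirds of pips sit in correlated
pairs; HH stimuli get low fillers, LL high, HL/LH half each, equalizing
level statistics across the four kinds. Event traces are convolved with a
boxcar of the pip duration (default 50 ms; 40 and 20 ms used by some
analyses). Partners falling off the frequency grid are dropped and
counted (`PipStats.n_dropped`), so rate checks can correct for the band
edge; overlapping pips on one channel are resolved by letting the
later-starting pip overwrite (keeping levels in {0, 0.5, 1}), with
collisions counted. Pairs do not chain: a partner never spawns its own
partner.

**Triplet gliders.** Binary masks whose only structure is a third-order
correlation over a three-point glider: two frequency-adjacent elements at
one frame plus one displaced element at the next frame (converging), or
the time-mirror (diverging), with orientation selecting the +-1 frequency
displacement. Boundary elements are i.i.d.; each interior element is set
so the product of the three centred elements equals the parity, which
makes the glider product exact everywhere while all pairwise covariances
vanish in expectation.

**Tone sweeps.** Deterministic ascending/descending lines of
time-frequency elements, one element per 1/6-s frame, and their sum; the
sum requires a grid on which the two lines never coincide (16 steps/octave
in the original design; the constructor raises if they would).

**Envelopes and rendering.** Masks are zero-order-hold upsampled to 20 kHz
and smoothed with a linear-phase moving average (25 ms for ternary
stimuli, 0.5 ms for binary/pip stimuli). A moving average was chosen over
a recursive low-pass because the description names only a cutoff, and the
boxcar preserves the [0, 1] envelope range exactly. Carrier phases are
all zero (pure sine phase). Rendered waveforms are peak-normalized per
file, with the pre-normalization peak kept in metadata.

## Mask analyses

`empirical_mask_autocorr` computes centred sample covariances using only
fully overlapping elements. Ternary {0, 0.5, 1} masks are rescaled by 2
after centring so the empirical map shares the +-1 scale of the closed
form above; binary masks are only centred (a Bernoulli(+-1/2) base has
variance 1/4).

The tracking-heuristic analysis (`pattern_occurrence`) classifies, at 1-ms
resolution, the intensity pair (value(f, t), value(f+d, t+delay)) as
high-high, low-low, high-low or low-high (high = 1, low = 0; the 0.5
background is excluded), separately in the direction of the imposed
correlation ("with", +d) and against it (-d); the net occurrence is the
with-fraction minus the against-fraction. Counting is per millisecond, so
a pip contributes once per sample of its duration. On ternary stimuli the
net HH and LL signals carry the sign of Q; on negative-correlation pip
stimuli the HH signal is weak while HL and LH carry the structure — the
observation that a track-the-loud-frequencies heuristic cannot explain
reversed percepts for negative correlations.

## Motion-energy unit and opponency

The unit convolves two temporal filters with the envelopes of two adjacent
frequency channels and squares the sum:

    r(t) = ((f1 * S1)(t) + (f2 * S2)(t))^2
    f1(t) = t^2 / tau^3 exp(-t / tau),   f2(t) = f1(t - T) Theta(t - T)

with tau = 20 ms (f1 peaks at 2 tau = 40 ms) and T = 40 ms. S1 is the
upper and S2 the lower channel: delaying the lower channel's signal aligns
it with energy that subsequently arrives above, making the unit
upward-selective. The opponent signal subtracts the frequency-flipped
unit: r_opp = (f1*S1 + f2*S2)^2 - (f2*S1 + f1*S2)^2.

The model consumes centred (+-1 scale) envelope traces directly as
spectrogram rows; no cochlear model is attempted. Convolutions run on a
1-ms grid with kernels truncated at T + 10 tau (residual tail mass below
1e-3); response means discard a burn-in of T + 5 tau.

For stimulus ensembles whose covariance is a delta of amplitude beta at
zero lag plus deltas of amplitude alpha at +-(delta_f, delta_t), the
time-averaged opponent response is proportional to alpha: the beta
(non-directional) term cancels in the subtraction. Two identities follow
and are verified numerically: <r_opp> inverts under direction reversal and
under correlation inversion, hence

    <r_opp(-alpha, dt, df)> = <r_opp(alpha, dt, -df)>

`symmetry_check` measures the worst-case discrepancy of that identity, in
pooled-standard-error units, over a delay sweep (default 20-100 ms),
using a two-channel Poisson impulse ensemble in which each initiator pairs
with an other-channel partner with probability |alpha|/beta and sign
sign(alpha); unpaired events keep both channel rates at beta so
single-channel statistics are independent of alpha. Run without the
opponent subtraction, the same statistic exposes the single unit's
asymmetry — the control that shows the symmetry is a property of
opponency, not of the ensemble. `tuning_sweep` instead drives the model
with multi-channel correlated-pip masks from the stimulus module,
averaging over all adjacent channel pairs; its "random" control shuffles
channel order, which destroys cross-channel correlations while preserving
per-channel statistics.

## Speech pipeline

Spectrograms use 25-ms non-overlapping frames (40 frames/s) evaluated at
20 log-spaced frequencies per octave from 100 Hz to 6400 Hz; the default
path zero-pads each frame (>= 4x) and interpolates the FFT magnitude onto
the log axis, with an exact per-bin Fourier evaluation available as a
cross-check. Amplitudes are used linearly (not in dB) throughout.

Tone change is estimated by Horn-Schunck optical flow along the frequency
axis between consecutive frames: the standard Jacobi iteration minimizing
the brightness-constancy residual plus a smoothness penalty (weight 1.0,
100 iterations — conventional defaults, recorded in output metadata),
averaged over frequency to one scalar per frame pair, positive for energy
moving toward higher frequencies. A constant spectrogram returns zeros.

The binarized pipeline thresholds the spectrogram with Otsu's method
(single global threshold maximizing between-class variance), then for
each intensity pattern (HH, LL, HL, LH) counts upward-directed
occurrences ((f, t) with (f+1, t+1)) minus downward-directed ones ((f, t)
with (f-1, t+1)), excluding boundary rows so the four frequency-averaged
net traces sum to zero exactly. The continuous variant feeds temporal
derivatives F = A_t - A_{t-1} into a half-rectified
Hassenstein-Reichardt correlator per sign pair. Each net trace is
correlated (Pearson) with the tone-change trace; corpus results pool all
frames before computing r (per-snippet averaging is possible by calling
the stages per file).

## Synthetic data

The chirp generator stands in for speech snippets: n bands at octave
spacings, each a cluster of three partials spread over `band_width`
octaves, all sweeping together at `sweep_rate` octaves/s, plus white
noise. Defaults: 3 bands, 0.02-octave clusters, 1.5 octaves/s, 1.5 s,
noise SD 0.1. The narrow clusters place the three partials a few hertz
apart, so each band beats slowly; this amplitude texture riding on the
frequency sweep is what gives the derivative-based correlator nonzero
cross-pattern (HL/LH) signals, as the amplitude texture of real speech
does. Wide smooth bands translating slowly produce structurally zero net
cross-pattern signals (their onset and offset ramps cancel by time
symmetry), which is why the defaults favour narrow beating lines. With
`f_start=None` the bands are placed at the geometric centre of the
feasible range so the whole sweep stays inside the 100-6400 Hz analysis
window.

What the generator does not emulate: harmonicity (bands are at octave
spacings, not a true F0 series), formant structure, syllabic amplitude
envelopes, pauses, or any linguistic content. Passing the sign-structure
checks on this corpus therefore shows that the pipeline recovers the
direction of spectrotemporal energy flow from band-structured sounds with
speech-like amplitude texture — not that any particular correlation value
measured on a real corpus is reproduced.

The simulated observer replaces human listeners with a lapse-logistic
link on the time-mean opponent response, P(rising) = lapse/2 +
(1 - lapse) logistic(gain x + bias), sampled as Bernoulli choices;
`fit_observer` recovers (gain, bias) by maximum likelihood (Nelder-Mead on
the clipped log-likelihood). Driven by the opponent model, the observer
inherits its symmetry: P(rising) > 0.5 for upward-positive and
downward-negative stimuli, < 0.5 for the other two, ~0.5 for shuffled
controls, and rises monotonically with coherence for upward-positive
stimuli with the downward-negative curve as its mirror.

## Numerical and scale choices

- The carrier comb is taken as 200-6400 Hz at 15 steps/octave (76
  carriers); the stated frequency endpoints are treated as authoritative
  for the octave span.
- Pip-rate checks run on 7600 channel-seconds (76 channels x 100 s);
  rates count partner events beyond the top band edge so they measure the
  generative process rather than the finite grid.
- Mask-statistics checks use ~1.2e5-element masks (3-standard-error
  bands).
- Symmetry and tuning checks use 40 trials x 4 s ensembles (or ~8-10
  trials for tuning curves), sizes at which the 3-SE criteria are
  well-resolved in seconds of CPU.
- Random numbers come from numpy's PCG64 `default_rng`; every public
  generator takes an explicit seed, and per-trial sub-seeds are drawn from
  a single stream so whole pipelines are bit-reproducible.
- Degenerate inputs: constant spectrograms binarize with an error (Otsu
  undefined) but flow returns zeros; empty or mis-sized masks, negative
  rates, out-of-range coherence and off-grid frequencies raise
  `ValueError` at construction.

## Known limitations

- The motion-energy unit is a deliberately minimal two-channel model; no
  cochlear filtering, adaptation, or population readout.
- The 3-SE property checks are statistical: with fixed seeds they are
  deterministic, but the max-over-delays symmetry statistic would exceed
  3 for roughly 1% of seeds under the null.
- The speech pipeline's headline correlations on real corpora depend on
  corpus content; this package reproduces the sign structure on synthetic
  fixtures only, and corpus WAVs can be analysed via the same CLI when
  available.
- Loudness equalization is a table interpolation at 60 phon, not a full
  loudness model; it is normalized at 1 kHz and applied after envelope
  smoothing (the two operations commute).
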