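# Methods

This note documents the models, defaults, and numerical choices behind
`breathturn`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model and repair chain

The respiration belt measures chest circumference in arbitrary units at a
nominal 200 Hz. Saturation appears as runs of identical extreme values when
the sensor rails, typically during strong inspirations. The repair chain
is:

1. **Smoothing** — centered 50-bin moving average (250 ms at 200 Hz). Even
   window lengths are centered on the leading sample (a 50-bin window
   covers `[i−25, i+24]`), which makes results bit-reproducible.
2. **Plateau flagging** — maximal runs where the absolute first difference
   of the smoothed signal is within `deriv_tol` (default `1e-9` of the
   amplitude range — an exact null derivative is fragile in float
   arithmetic), at least `min_run = 10` samples (50 ms) long, *and* whose
   level lies in the top or bottom amplitude decile. The decile restriction
   exists because flat mid-range breathing pauses are not sensor faults and
   must not be "repaired". Because smoothing shrinks a plateau's flat core
   by the window length, detected runs are re-expanded by half a window on
   each side before repair.
3. **Spline repair** — a cubic interpolating spline fitted on *all*
   non-flagged samples of the session (not just the gap neighbourhood),
   evaluated inside the flagged runs. Runs touching either end of the
   recording are filled by holding the nearest intact value instead of
   extrapolating, with a warning.
4. **Resampling** — linear interpolation onto a 1 ms grid spanning the same
   time range.
5. **Session alignment** — the belt recording stops with the scanner, so
   the trace is aligned by its end: `origin = session_duration −
   trace_duration`.
6. **Peak detection** — local maxima with prominence at least 10% of the
   5th–95th percentile amplitude range and pairwise separation at least
   1.0 s (the shortest plausible breath). No peak-extraction criteria are
   inherited from elsewhere; these are this package's defaults, exposed in
   the configuration and echoed to the run log.

Half-open sample intervals `[start, stop)` and 0-based indexing are used
throughout.

A known limitation, shared with any interpolation-based repair: a clipped
breath maximum is a sharp rise/recoil asymmetry that a smooth spline cannot
fully reconstruct, so repaired maxima carry timing errors on the order of
100 ms. This is why peak-detection accuracy statements (98% of maxima
within 50 ms) are made for the clean, unsaturated case; saturated maxima
contribute extra Δt dispersion, as they would in real data.

## IPU segmentation

An Inter-Pausal Unit is a stretch of continuous speech bounded by silences
longer than 200 ms. Frames of the RMS envelope (25 ms frames, 10 ms hop by
default) at or above `coefficient × mean(envelope)` are speech; the
coefficient is participant-specific and nominally within 0.20–0.95. The
pause rule is strict — a silence splits speech only when *longer* than
200 ms; exactly 200 ms merges. Speech runs shorter than `min_ipu = 100 ms`
are discarded as click artifacts (a package decision; the pause definition
itself says nothing about minimum IPU length). Boundaries are reported at
frame-edge resolution. Audio denoising is out of scope: the module assumes
denoised input, and the synthetic generator injects residual noise instead.
An optional grid search of the coefficient against annotated IPUs is
provided as a convenience extension.

## Event classification and Δt

IPU onsets are mapped from block-relative to session time by adding the
block onset from the session log. For each participant IPU onset, the
respiration maximum minimizing `|t_peak − t_onset|` is `Resp+` and linked;
never-linked maxima are `Resp−` — a partition of the peak set. There is no
maximum matching window: the nearest maximum is `Resp+` however far away,
and extreme lags are handled downstream by the MAD filter. A maximum
nearest to several onsets appears once in the event list but contributes
one Δt record per IPU (events partition maxima; Δt is per IPU). Equidistant
ties break toward the earlier maximum, since inhalation precedes speech
physiologically; tie frequency is logged. Interlocutor IPUs are carried
through to the GLM event export (`ipu_interlocutor`, with true durations)
but never participate in classification. `resp_plus`/`resp_minus` rows have
duration exactly 0.

## Lag statistics

- **Outlier rejection**: single pass; remove `x` with `|x − median| >
  3 · c · MAD`, `c = 1.4826` by default so the MAD estimates a normal
  sigma (matching the default of common outlier routines); `--mad-scale
  raw` gives the unscaled reading. Zero MAD with non-identical values falls
  back to removing everything different from the median, logged.
- **Normality**: Lilliefors-corrected Kolmogorov–Smirnov test, because the
  normal's parameters are estimated from the sample.
- **Skewness**: adjusted Fisher–Pearson `g1` with D'Agostino's test of zero
  skewness.
- **Density mode**: argmax of a Gaussian KDE (Silverman bandwidth by
  default, overridable in seconds) on a 1 ms grid over the data range.
  Reported only for samples of at least 50 lags, so per-session summaries
  omit it and cohort-level pooling reports it.
- **Condition comparison**: both pooled-variance (Student) and
  unequal-variance (Welch) two-sample tests are reported, computed on the
  cleaned sample. Cohort pooling is reported at two aggregation levels —
  all Δt records pooled, and the distribution of per-session mean lags —
  because either could be the unit of analysis; neither is privileged.
  Statistics are computed after outlier removal, following the processing
  order of the text they implement.

## The synthetic generator

The generator's defaults are the study conditions the analysis targets; the
tests and the acceptance script run at these values.

- **Session**: 385 volumes × TR 1.205 s = 463.925 s, six 1-minute
  conversation blocks (onsets 20 s + k·72 s), alternating human/robot
  interlocutor conditions.
- **Conversation**: one IPU per turn; turn durations gamma-distributed with
  mean 4.0 s (min 1.0 s), gaps mean 1.5 s (min 0.25 s — always above the
  pause rule), floor changes hands with probability 0.75. With the breath
  parameters below this yields ~30–35 participant IPUs and ~150 maxima per
  session, i.e. a Resp+ share near one fifth of all maxima, matching the
  regime the analysis is designed for. The expected IPU count follows
  `duration / (mean_turn + mean_gap)`.
- **Breath cycles**: piecewise segments with maxima exactly at the
  ground-truth peak times — a raised-cosine inhalation (0.2–0.5 s) into
  each maximum and a quadratic-recoil exhalation (sharp initial drop that
  slows toward the trough, like passive expiration; exhale draws 1.5–4.0 s).
  A physiological ODE model is deliberately not used: only peak timing and
  rise/fall asymmetry matter downstream. Amplitudes are uniform on 0.5–1.0
  a.u. with a 10% mixture of deep inspirations (1.2–1.6 a.u.) — these are
  the breaths that hit the saturation rail (default 1.1 a.u.) for several
  hundred ms, long enough to survive the 250 ms smoothing used by plateau
  flagging. Brownian baseline drift (0.005 a.u./√s) and white noise
  (0.01 a.u.) are added last, so the clean waveform's argmax equals the
  ground-truth peak time within one sample.
- **Lag model**: `Δt`-generating lags are drawn from a negated gamma with
  density mode −0.200 s, standard deviation 0.10 s, shape 3 (skewness
  −1.15) — left-skewed, so the breath maximum most often precedes speech
  onset slightly, with occasional much-earlier inhalations. The spread is a
  package choice: the observed corpus dispersion (~0.17 s) includes peak-
  and onset-timing measurement error that the generator models separately,
  and a mode recoverable to ±25 ms by a KDE argmax at n ≈ 1000–2000
  requires a density about this sharp (verified by direct numerical
  analysis of KDE mode-estimation error before fixing the default).
- **Coupling**: 99% of participant IPUs get a maximum at `onset + lag`;
  decoupled turns (speech launched mid-exhale) are rare. Metabolic maxima
  fill the remaining time and are kept ≥ 1 s from every participant onset
  by construction so ground-truth labels are unambiguous (threshold
  configurable). Uncoupled IPUs necessarily link to a metabolic maximum
  ≥ 1 s away and are removed by the MAD filter; together with the gamma
  tail this puts the expected removed fraction near 4%, under the 5%
  working bound.
- **Envelope**: per-frame RMS of a speech component (present for the
  covered fraction of the frame) plus residual noise; frame values are
  chi-square concentrated because a frame RMS averages ~400 audio samples.
  With zero noise the envelope is exactly zero outside IPUs.
- **Sulcus images**: a bright background with one dark 8-connected curve
  running laterally from a fundus seed near the midline with sinusoidal
  anteroposterior modulation, plus labelled probe points (on-path,
  sub-pixel from the seed, ±5 px along the anterior axis). PNG export is
  16-bit grayscale with a JSON sidecar of the true path and probes.

All randomness derives from one integer seed per generator call; the
pipeline spawns one child stream per call from its session seed
(`numpy.random.SeedSequence`), so fixed seeds give byte-identical outputs.

What the generator does *not* emulate: linguistic structure, overlapping
speech, reverberant scanner acoustics, cardiac contamination of the belt,
non-stationary breathing rates, or multi-IPU breath groups (each turn is
one IPU, so nearly every IPU onset has its own inhalation). Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical structure, not robustness to every property of real recordings.

## Sulcus tracing

From a seed at the fundus (the grey-matter pixel of the sulcus closest to
the midline — chosen manually or as the darkest in-band pixel nearest the
midline column), the tracer repeatedly steps to the lowest-intensity
8-neighbour that is unvisited and centrifugal, stopping at the border, a
length cap, or when the best candidate is brighter than `stop_intensity`.
Numerical choices, all exposed as parameters:

- *Centrifugality* is strict by default (distance from the midline column
  never decreases). A 1 px slack variant is available for sulci that bend
  back toward the midline, but with slack the greedy walk can step backward
  onto a skipped neighbour of the line and trap itself against its own
  trail, so strictness is the default.
- *Ties* break by preferring the continuation of the previous step
  direction, then clockwise angular order.
- *Stop intensity* defaults to the midpoint between the darkest band
  (0.1th percentile, deep sulcal grey) and the median (bulk tissue). An
  Otsu split is not used: the sulcal band can be a tiny minority class and
  the Otsu threshold then lands inside the bulk mode.
- The neighbourhood is 8-connected; tracing is 2-D on one axial slice.

Peak categorization evaluates in fixed order: `FUNDUS` if the peak is
within 1 px of the seed, else `ON_LINE` if within 1 px of the path, else
`ANTERIOR`/`POSTERIOR` by the sign of the projection of (peak − nearest
path point) onto the anterior axis (default +y under the declared slice
orientation). Categories are invariant to global intensity offsets and to
left–right mirroring with the matching hemisphere flip.

## Problem sizes and determinism

The acceptance tests pool cohorts of 10 sessions of 2400 s (~2200 lags per
generating mode) for mode-recovery checks, and the acceptance script runs a
25-participant × 4-session synthetic corpus at the default session length —
sizes at which the KDE mode estimator's sampling error is comfortably
inside the ±25 ms bands used. Full runs are deterministic: the same
configuration and seed reproduce byte-identical output files, verified at
the hash level in the test suite.
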