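"""Synthetic conversations, respiration traces, speech envelopes, and sulcus
images with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: asymmetric breath cycles (fast 200-500 ms inhalations, prolonged
exhalations), inhalation maxima locked to the scanned participant's speech
onsets with a configurable left-skewed lag distribution peaking near -200 ms,
amplitude-rail saturation plateaus, turn-taking IPU sequences separated by
pauses longer than 200 ms, and dark curvilinear sulcus paths on bright
axial-slice images.

All randomness flows from one integer seed per generator call through
``numpy.random.default_rng``; the pipeline derives per-call child seeds from
its session seed with ``numpy.random.SeedSequence`` (one child stream per
generator call), so fixed seeds reproduce byte-identical artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .ipu_segment import INTERLOCUTOR, IPU, PARTICIPANT, Envelope
from .resp_preproc import RespirationTrace

log = logging.getLogger(__name__)

SPEECH_COUPLED = "speech_coupled"
METABOLIC = "metabolic"

#: metabolic maxima are kept at least this far from participant IPU onsets
DEFAULT_ONSET_GUARD = 1.0
#: minimum spacing between a metabolic maximum and any coupled maximum
#: (keeps ground-truth labels resolvable by peak detection)
MIN_PEAK_SPACING = 1.2
#: minimum spacing between two speech-coupled maxima — speech breathing can
#: cycle fast when turns come in quick succession
MIN_COUPLED_SPACING = 0.8
#: fraction of participant IPUs whose onset is launched from an inhalation
#: maximum; decoupled turns (speech started mid-exhale) are rare.  Together
#: with the heavy left tail of the lag model this keeps MAD-rejected lags
#: well under the 5% working bound
DEFAULT_COUPLED_FRACTION = 0.99


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class TurnParams:
    """Stochastic turn-taking model: one IPU per turn, gamma-distributed turn
    and gap durations, stochastic speaker alternation."""

    mean_turn: float = 4.0     # s
    mean_gap: float = 1.5      # s; always > the 200 ms pause rule
    min_turn: float = 1.0
    min_gap: float = 0.25
    turn_shape: float = 4.0    # gamma shape of (turn - min_turn)
    gap_shape: float = 2.0
    p_switch: float = 0.75     # probability the floor changes hands

    def __post_init__(self) -> None:
        if self.mean_turn <= self.min_turn or self.mean_gap <= self.min_gap:
            raise ValueError("mean durations must exceed their minima")
        if self.min_gap <= 0.2:
            raise ValueError("min_gap must exceed the 200 ms pause rule")


@dataclass
class BreathCycleParams:
    """Asymmetric breath cycle: short, rapid inhalations and slow exhalations."""

    inhale_dur_range: tuple[float, float] = (0.2, 0.5)
    exhale_dur_range: tuple[float, float] = (1.5, 4.0)
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    #: occasional much deeper inspirations (large tidal volume); these are
    #: the breaths that drive the belt into its measurement rail
    deep_fraction: float = 0.10
    deep_amplitude_range: tuple[float, float] = (1.2, 1.6)
    baseline_drift_sd: float = 0.005   # a.u. per sqrt(s), Brownian baseline
    noise_sd: float = 0.01             # a.u., additive white noise

    def __post_init__(self) -> None:
        for name in (
            "inhale_dur_range", "exhale_dur_range", "amplitude_range",
            "deep_amplitude_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: require low <= high")
        if self.inhale_dur_range[0] <= 0 or self.exhale_dur_range[0] <= 0:
            raise ValueError("durations must be strictly positive")


@dataclass
class LagModel:
    """Distribution of the speech-onset lag (peak time minus IPU onset).

    The default family is a negated, shifted gamma whose density mode sits at
    ``mode`` (-200 ms): left-skewed, so the breath maximum most often
    precedes speech onset with occasional much-earlier inhalations.
    ``spread`` is the distribution's standard deviation; ``shape`` the gamma
    shape (skewness = -2/sqrt(shape)).
    """

    family: str = "shifted_negative_gamma"
    mode: float = -0.200   # s
    spread: float = 0.10   # s (standard deviation)
    shape: float = 3.0

    _FAMILIES = ("shifted_negative_gamma", "gaussian", "point_mass")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown lag family {self.family!r}")
        if self.family != "point_mass" and self.spread <= 0:
            raise ValueError("spread must be positive")

    @property
    def skew_direction(self) -> str:
        return {"shifted_negative_gamma": "left"}.get(self.family, "none")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point_mass":
            return np.full(n, self.mode)
        if self.family == "gaussian":
            return rng.normal(self.mode, self.spread, n)
        theta = self.spread / math.sqrt(self.shape)
        shift = self.mode + (self.shape - 1.0) * theta  # gamma mode maps to `mode`
        return shift - rng.gamma(self.shape, theta, n)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_peak_times: list[float]
    true_labels: list[str]                 # SPEECH_COUPLED | METABOLIC, per peak
    true_lags: list[Optional[float]]       # per peak; None for metabolic
    true_ipu_onsets: list[Optional[float]]  # per peak; None for metabolic
    saturated_intervals: list[tuple[float, float]] = field(default_factory=list)
    ipu_list: list[IPU] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.true_peak_times)
        if not (len(self.true_labels) == len(self.true_lags) == len(self.true_ipu_onsets) == n):
            raise ValueError("per-peak ground-truth fields must align")
        for start, stop in self.saturated_intervals:
            if not start < stop:
                raise ValueError("saturated intervals must be non-empty [start, stop)")
        starts = [s for s, _ in self.saturated_intervals]
        stops = [e for _, e in self.saturated_intervals]
        for (s, e), (s2, _) in zip(self.saturated_intervals, self.saturated_intervals[1:]):
            if s2 < e:
                raise ValueError("saturated intervals must be disjoint")

    @property
    def coupled_mask(self) -> np.ndarray:
        return np.array([lab == SPEECH_COUPLED for lab in self.true_labels])

    def to_dict(self) -> dict:
        return {
            "true_peak_times": self.true_peak_times,
            "true_labels": self.true_labels,
            "true_lags": self.true_lags,
            "true_ipu_onsets": self.true_ipu_onsets,
            "saturated_intervals": [list(iv) for iv in self.saturated_intervals],
            "ipu_list": [
                {
                    "onset": i.onset,
                    "offset": i.offset,
                    "speaker": i.speaker,
                    "trial_id": i.trial_id,
                }
                for i in self.ipu_list
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_peak_times=list(d["true_peak_times"]),
            true_labels=list(d["true_labels"]),
            true_lags=list(d["true_lags"]),
            true_ipu_onsets=list(d["true_ipu_onsets"]),
            saturated_intervals=[tuple(iv) for iv in d["saturated_intervals"]],
            ipu_list=[IPU(**kw) for kw in d["ipu_list"]],
        )


# ---------------------------------------------------------------------------
# conversation


def generate_conversation(
    duration: float,
    turn_params: Optional[TurnParams] = None,
    seed: int = 0,
) -> list[IPU]:
    """Simulate a turn-taking conversation as a list of IPUs.

    Speakers alternate stochastically; within one speaker, consecutive IPUs
    are separated by silences longer than 200 ms; all IPUs lie inside
    ``[0, duration]``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = turn_params or TurnParams()
    rng = np.random.default_rng(seed)
    ipus: list[IPU] = []
    speaker = PARTICIPANT if rng.random() < 0.5 else INTERLOCUTOR
    t = float(rng.uniform(0, params.min_gap))
    while True:
        remaining = duration - t
        if remaining < params.min_turn:
            break
        dur = params.min_turn + rng.gamma(
            params.turn_shape, (params.mean_turn - params.min_turn) / params.turn_shape
        )
        dur = min(dur, remaining)
        ipus.append(IPU(onset=t, offset=t + dur, speaker=speaker))
        gap = params.min_gap + rng.gamma(
            params.gap_shape, (params.mean_gap - params.min_gap) / params.gap_shape
        )
        t += dur + gap
        if rng.random() < params.p_switch:
            speaker = INTERLOCUTOR if speaker == PARTICIPANT else PARTICIPANT
    if not ipus:
        log.warning("duration %.3f s too short to place a single IPU", duration)
    return ipus


# ---------------------------------------------------------------------------
# respiration


def generate_respiration(
    ipu_list: Sequence[IPU],
    breath_params: Optional[BreathCycleParams] = None,
    lag_model: Optional[LagModel] = None,
    coupled_fraction: float = DEFAULT_COUPLED_FRACTION,
    sampling_rate: float = 200.0,
    seed: int = 0,
    duration: Optional[float] = None,
    onset_guard: float = DEFAULT_ONSET_GUARD,
) -> tuple[RespirationTrace, GroundTruth]:
    """Simulate a belt trace whose maxima are coupled to speech onsets.

    Each participant IPU receives, with probability ``coupled_fraction``, a
    respiration maximum at ``onset + lag`` with the lag drawn from
    ``lag_model``; the remaining time is filled with metabolic cycles whose
    maxima stay at least ``onset_guard`` seconds from every participant IPU
    onset (so ground-truth labels are unambiguous).  The waveform is built
    from piecewise raised-cosine segments — a fast rise to each maximum over
    an inhalation drawn from ``inhale_dur_range`` and a slow fall to the next
    trough — so every local maximum of the clean signal sits exactly at a
    ground-truth peak time.
    """
    if sampling_rate < 50:
        raise ValueError("sampling_rate must be >= 50 Hz")
    bp = breath_params or BreathCycleParams()
    lm = lag_model or LagModel()
    rng = np.random.default_rng(seed)

    ipus = list(ipu_list)
    onsets_all = [i.onset for i in ipus]
    if onsets_all != sorted(onsets_all):
        raise ValueError("ipu_list must be sorted by onset")
    participant = [i for i in ipus if i.speaker == PARTICIPANT]
    onsets = np.array([i.onset for i in participant])
    if duration is None:
        duration = (max((i.offset for i in ipus), default=5.0)) + 5.0

    # --- coupled maxima ---------------------------------------------------
    coupled = rng.random(len(participant)) < coupled_fraction
    lags = lm.sample(len(participant), rng)
    peak_times: list[float] = []
    peak_lags: list[float] = []
    peak_onsets: list[float] = []
    margin = bp.inhale_dur_range[0] + 0.1
    for k in np.flatnonzero(coupled):
        t = onsets[k] + lags[k]
        if not margin <= t <= duration - 0.5:
            continue  # peak would fall off the recording; leave IPU uncoupled
        if peak_times and t - peak_times[-1] < MIN_COUPLED_SPACING:
            log.debug("coupled maxima collide near %.2f s; later one dropped", t)
            continue
        peak_times.append(float(t))
        peak_lags.append(float(lags[k]))
        peak_onsets.append(float(onsets[k]))

    coupled_times = np.array(peak_times)

    # --- metabolic fill ---------------------------------------------------
    def draw_cycle() -> float:
        return float(rng.uniform(*bp.inhale_dur_range) + rng.uniform(*bp.exhale_dur_range))

    metabolic: list[float] = []
    t = float(rng.uniform(0.3, 0.8))
    while t < duration - margin:
        near_coupled = (
            len(coupled_times) > 0
            and np.min(np.abs(coupled_times - t)) < MIN_PEAK_SPACING
        )
        near_onset = len(onsets) > 0 and np.min(np.abs(onsets - t)) < onset_guard
        if not (near_coupled or near_onset):
            metabolic.append(t)
        else:
            log.debug("metabolic cycle near %.2f s dropped (guard)", t)
        t += draw_cycle()

    times = np.array(sorted(metabolic) + peak_times)
    order = np.argsort(times, kind="stable")
    labels = np.array([METABOLIC] * len(metabolic) + [SPEECH_COUPLED] * len(peak_times))
    lag_col = np.array([None] * len(metabolic) + peak_lags, dtype=object)
    onset_col = np.array([None] * len(metabolic) + peak_onsets, dtype=object)
    times, labels = times[order], labels[order]
    lag_col, onset_col = lag_col[order], onset_col[order]

    samples = _render_breath_waveform(times, duration, bp, sampling_rate, rng)
    if bp.noise_sd > 0:
        samples = samples + rng.normal(0.0, bp.noise_sd, len(samples))

    trace = RespirationTrace(samples=samples, rate=sampling_rate, origin=0.0)
    truth = GroundTruth(
        true_peak_times=[float(v) for v in times],
        true_labels=[str(v) for v in labels],
        true_lags=[None if v is None else float(v) for v in lag_col],
        true_ipu_onsets=[None if v is None else float(v) for v in onset_col],
        saturated_intervals=[],
        ipu_list=ipus,
    )
    return trace, truth


def _render_breath_waveform(
    peak_times: np.ndarray,
    duration: float,
    bp: BreathCycleParams,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise raised-cosine waveform with maxima exactly at ``peak_times``."""
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    if len(peak_times) == 0:
        return np.zeros(n)

    # knots alternate trough -> peak; inhalations are fast, exhalations take
    # the rest of the inter-peak gap
    knot_t: list[float] = []
    knot_v: list[float] = []
    prev = 0.0
    amp_lo, amp_hi = bp.amplitude_range
    drift = 0.0
    last_knot_time = 0.0

    def advance_drift(to_time: float) -> float:
        nonlocal drift, last_knot_time
        dt = max(0.0, to_time - last_knot_time)
        drift += bp.baseline_drift_sd * math.sqrt(dt) * rng.standard_normal()
        last_knot_time = to_time
        return drift

    knot_t.append(0.0)
    knot_v.append(0.0)
    for i, p in enumerate(peak_times):
        gap = p - prev
        inhale = min(float(rng.uniform(*bp.inhale_dur_range)), 0.6 * gap)
        trough_t = p - inhale
        if trough_t <= knot_t[-1]:
            trough_t = 0.5 * (knot_t[-1] + p)
        knot_t.append(trough_t)
        knot_v.append(advance_drift(trough_t))
        if rng.random() < bp.deep_fraction:
            amp = float(rng.uniform(*bp.deep_amplitude_range))
        else:
            amp = float(rng.uniform(amp_lo, amp_hi))
        knot_t.append(float(p))
        knot_v.append(amp + advance_drift(p))
        prev = float(p)
    # final exhale back to baseline
    tail = min(duration, prev + float(rng.uniform(*bp.exhale_dur_range)))
    if tail > knot_t[-1]:
        knot_t.append(tail)
        knot_v.append(advance_drift(tail))
    if duration > knot_t[-1]:
        knot_t.append(duration)
        knot_v.append(knot_v[-1])

    kt = np.array(knot_t)
    kv = np.array(knot_v)
    # a knot is a peak iff it was appended as such: peaks sit at odd slots
    # after the initial baseline knot and before the tail knots
    is_peak = np.zeros(len(kt), dtype=bool)
    is_peak[2:2 + 2 * len(peak_times):2] = True
    idx = np.clip(np.searchsorted(kt, t, side="right") - 1, 0, len(kt) - 2)
    t0, t1 = kt[idx], kt[idx + 1]
    v0, v1 = kv[idx], kv[idx + 1]
    span = np.where(t1 > t0, t1 - t0, 1.0)
    u = np.clip((t - t0) / span, 0.0, 1.0)
    # inhalation: smooth raised-cosine rise into the maximum; exhalation:
    # quadratic recoil — a sharp initial drop that slows toward the trough,
    # like passive expiration (keeps the maximum crisp at the knot)
    rise = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))
    fall = v1 + (v0 - v1) * (1.0 - u) ** 2
    return np.where(is_peak[idx + 1], rise, fall)


def apply_saturation(
    trace: RespirationTrace, rail_low: float, rail_high: float
) -> tuple[RespirationTrace, list[tuple[int, int]]]:
    """Clamp a trace to sensor rails and report the clipped runs.

    Returns the clamped trace and the maximal half-open sample intervals
    where clamping changed at least one sample.
    """
    if not rail_low < rail_high:
        raise ValueError("require rail_low < rail_high")
    x = trace.samples
    clipped = np.clip(x, rail_low, rail_high)
    changed = clipped != x
    if changed.all():
        raise ValueError("rails exclude the entire signal range (everything saturated)")
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(changed)
    while i < n:
        if changed[i]:
            j = i
            while j < n and changed[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    mask = trace.saturation_mask | changed
    out = RespirationTrace(
        samples=clipped, rate=trace.rate, origin=trace.origin, saturation_mask=mask
    )
    return out, intervals


# ---------------------------------------------------------------------------
# speech envelope


def render_rms_envelope(
    ipu_list: Sequence[IPU],
    duration: Optional[float] = None,
    frame: float = 0.025,
    hop: float = 0.010,
    speech_level: float = 1.0,
    noise_level: float = 0.05,
    seed: int = 0,
) -> Envelope:
    """Synthesize an RMS envelope directly from IPU intervals.

    Stands in for denoised conversational audio: each frame's value is the
    RMS of a speech component (present for the fraction of the frame covered
    by an IPU) plus residual noise.  With ``noise_level = 0`` the envelope is
    exactly zero outside IPUs.
    """
    if not speech_level > noise_level >= 0:
        raise ValueError("require speech_level > noise_level >= 0")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = max((i.offset for i in ipu_list), default=1.0) + 0.5
    n_frames = max(1, int(math.floor((duration - frame) / hop)) + 1)
    starts = np.arange(n_frames) * hop
    centers = starts + frame / 2.0
    coverage = np.zeros(n_frames)
    for ipu in ipu_list:
        lo = np.clip(ipu.onset, starts, starts + frame)
        hi = np.clip(ipu.offset, starts, starts + frame)
        coverage += (hi - lo) / frame
    coverage = np.clip(coverage, 0.0, 1.0)
    # a frame RMS averages many audio samples, so its sampling variability is
    # chi-square concentrated around the component level (m = samples/frame
    # at a nominal 16 kHz audio rate); speech level varies a little more
    # across frames than stationarity alone would give
    m = max(1, int(round(frame * 16000)))
    speech_amp = speech_level * (1.0 + 0.05 * rng.standard_normal(n_frames))
    noise_amp = noise_level * np.sqrt(rng.chisquare(m, n_frames) / m)
    values = np.sqrt(coverage * speech_amp**2 + noise_amp**2)
    return Envelope(times=centers, values=values)


# ---------------------------------------------------------------------------
# sulcus images


@dataclass
class SulcusCurveSpec:
    """Parametric sulcus curve: runs laterally from near the midline with a
    sinusoidal anteroposterior modulation."""

    start_offset: int = 6     # px from the midline column (the sulcus never
                              # reaches the midline at this slice height)
    extent: int = 44          # lateral run length, px
    amplitude: float = 4.0    # px, anteroposterior modulation
    cycles: float = 1.25
    row0: Optional[int] = None  # center row; defaults to the image middle
    hemisphere: str = "right"


def generate_sulcus_image(
    size: int = 128,
    path_spec: Optional[SulcusCurveSpec] = None,
    depth_contrast: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
    background: float = 0.8,
) -> tuple[np.ndarray, list[tuple[int, int]], dict[str, dict]]:
    """Render a bright axial-slice-like image with one dark sulcus path.

    Returns ``(image, true_path, probe_points)`` where the image is a float
    array indexed ``image[y, x]``, ``true_path`` is the ordered list of
    ``(x, y)`` path pixels starting at the fundus seed, and ``probe_points``
    maps probe names to ``{"xy": (x, y), "label": ...}`` with ground-truth
    categories (one on-path, one within a pixel of the seed, one offset to
    each side along the anterior axis).
    """
    spec = path_spec or SulcusCurveSpec()
    rng = np.random.default_rng(seed)
    if noise_sd >= depth_contrast:
        log.warning(
            "noise_sd %.3g >= depth_contrast %.3g: tracing is not guaranteed",
            noise_sd, depth_contrast,
        )
    midline_x = size // 2
    row0 = spec.row0 if spec.row0 is not None else size // 2
    sign = 1 if spec.hemisphere == "right" else -1
    x0 = midline_x + sign * spec.start_offset
    x1 = x0 + sign * spec.extent
    if not (0 <= min(x0, x1) and max(x0, x1) < size and 0 <= row0 < size):
        raise ValueError("path endpoints outside the image")
    if abs(spec.amplitude) * 2 * math.pi * spec.cycles / spec.extent > 1.0:
        raise ValueError("curve too steep to rasterize as an 8-connected chain")

    ts = np.linspace(0.0, 1.0, 8 * spec.extent)
    xs = x0 + sign * spec.extent * ts
    ys = row0 + spec.amplitude * np.sin(2 * math.pi * spec.cycles * ts)
    pix = np.stack([np.rint(xs), np.rint(ys)], axis=1).astype(int)
    path: list[tuple[int, int]] = []
    for x, y in pix:
        if path and (x, y) == path[-1]:
            continue
        path.append((int(x), int(y)))
    seen = set()
    path = [p for p in path if not (p in seen or seen.add(p))]
    for (xa, ya), (xb, yb) in zip(path, path[1:]):
        if max(abs(xa - xb), abs(ya - yb)) > 1:
            raise RuntimeError("rasterized path is not 8-connected")

    image = np.full((size, size), background, dtype=float)
    for x, y in path:
        image[y, x] = background - depth_contrast
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)

    seed_px = path[0]
    mid = path[len(path) // 2]
    probes = {
        "on_line": {"xy": (float(mid[0]), float(mid[1])), "label": "ON_LINE"},
        "near_seed": {
            "xy": (seed_px[0] + 0.4, seed_px[1] + 0.4),
            "label": "FUNDUS",
        },
        "anterior": {"xy": (float(mid[0]), float(mid[1] + 5)), "label": "ANTERIOR"},
        "posterior": {"xy": (float(mid[0]), float(mid[1] - 5)), "label": "POSTERIOR"},
    }
    return image, path, probes


def write_sulcus_png(path, image: np.ndarray) -> None:
    """Save a float image as 16-bit grayscale PNG (scaled to [0, 1] range)."""
    import imageio.v3 as iio

    scaled = np.clip(image, 0.0, 1.0)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def read_sulcus_png(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)), dtype=float)
    info = np.iinfo(np.uint16) if arr.max() > 255 else np.iinfo(np.uint8)
    return arr / info.max
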