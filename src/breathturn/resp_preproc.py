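"""Respiration-belt preprocessing: saturation repair, resampling, alignment,
and detection of respiration maxima.

The belt occasionally rails during strong inspirations, producing plateaus of
identical extreme values.  The repair chain mirrors the standard treatment:
smooth with a 50-bin (250 ms at 200 Hz) moving average, flag null-derivative
runs at extreme amplitudes as saturated, replace them with a cubic spline
fitted on all intact samples of the session, resample the repaired signal at
millisecond resolution, and align it to the session clock using the known
synchronization between the belt-signal offset and the end of the recording
session.  Respiration maxima (inspiration-to-expiration transitions) are then
extracted as prominent local maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BINS = 50       # 250 ms at 200 Hz
DEFAULT_MIN_RUN = 10           # 50 ms at 200 Hz
DEFAULT_MIN_SEPARATION = 1.0   # s; shortest plausible breath cycle
DEFAULT_PROMINENCE_FRAC = 0.10  # of the 5th-95th percentile amplitude range
EXTREME_DECILE = 0.10


class PeakLabel(str, Enum):
    RESP_PLUS = "resp_plus"
    RESP_MINUS = "resp_minus"
    UNLABELLED = "unlabelled"


@dataclass
class RespirationTrace:
    """Uniformly sampled belt signal.

    ``origin`` is the session-clock time of the first sample; the saturation
    mask marks samples that were flagged (and possibly repaired).
    """

    samples: np.ndarray
    rate: float
    origin: float = 0.0
    saturation_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.saturation_mask is None:
            self.saturation_mask = np.zeros(len(self.samples), dtype=bool)
        else:
            self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
            if len(self.saturation_mask) != len(self.samples):
                raise ValueError("saturation mask length mismatch")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Time span first-to-last sample, in seconds."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.n) / self.rate


@dataclass
class RespPeak:
    """One inspiration-to-expiration transition (respiration maximum)."""

    time: float
    amplitude: float
    label: PeakLabel = PeakLabel.UNLABELLED
    ipu_id: Optional[int] = None


def moving_average(trace: RespirationTrace, window_bins: int = DEFAULT_WINDOW_BINS) -> RespirationTrace:
    """Centered moving-average smoothing with shrinking windows at the edges.

    Even window lengths are centered on the leading sample: a 50-bin window
    covers samples ``[i-25, i+24]``.  Output length equals input length.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    x = trace.samples
    n = len(x)
    if window_bins > n:
        raise ValueError(f"window ({window_bins}) longer than signal ({n})")
    left = window_bins // 2
    right = window_bins - 1 - left
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return replace(trace, samples=smoothed)


def detect_saturation(
    smoothed: RespirationTrace,
    deriv_tol: Optional[float] = None,
    min_run: int = DEFAULT_MIN_RUN,
    extreme_decile: float = EXTREME_DECILE,
    expand_bins: int = 0,
) -> list[tuple[int, int]]:
    """Flag saturation plateaus as null-derivative runs at extreme amplitudes.

    Runs of ``min_run`` or more samples whose consecutive first differences
    are within ``deriv_tol`` *and* whose level lies in the top or bottom
    amplitude decile are returned as half-open sample intervals
    ``[start, stop)``.  ``expand_bins`` widens each run on both sides, which
    compensates for the shrinkage a moving-average filter applies to the
    flat core of a plateau (pass half the smoothing window).

    ``deriv_tol`` defaults to ``1e-9`` of the amplitude range: exactly-zero
    derivatives are fragile after float smoothing.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    x = smoothed.samples
    n = len(x)
    if n < 2:
        return []
    rng_amp = float(np.max(x) - np.min(x))
    if deriv_tol is None:
        deriv_tol = 1e-9 * rng_amp
    if deriv_tol < 0:
        raise ValueError("deriv_tol must be >= 0")
    lo_level = np.quantile(x, extreme_decile)
    hi_level = np.quantile(x, 1.0 - extreme_decile)

    flat = np.abs(np.diff(x)) <= deriv_tol
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < len(flat):
        if flat[i]:
            j = i
            while j < len(flat) and flat[j]:
                j += 1
            start, stop = i, j + 1  # samples [i, j+1)
            if stop - start >= min_run:
                level = float(np.mean(x[start:stop]))
                if level >= hi_level or level <= lo_level:
                    intervals.append(
                        (max(0, start - expand_bins), min(n, stop + expand_bins))
                    )
            i = j
        else:
            i += 1
    return _merge_intervals(intervals)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, stop in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def interpolate_gaps(
    trace: RespirationTrace, intervals: list[tuple[int, int]]
) -> RespirationTrace:
    """Replace flagged intervals with a cubic interpolating spline.

    The spline is fitted on *all* non-flagged samples of the session, so the
    repair leverages the full recording rather than the gap's immediate
    neighbourhood.  An interval touching either end of the signal cannot be
    bridged by interpolation; it is filled by holding the nearest intact
    value, with a warning.
    """
    n = trace.n
    if not intervals:
        return replace(trace, samples=trace.samples.copy())
    flagged = np.zeros(n, dtype=bool)
    for start, stop in intervals:
        if not (0 <= start < stop <= n):
            raise ValueError(f"interval [{start}, {stop}) outside trace of length {n}")
        flagged[start:stop] = True
    if flagged.mean() >= 0.5:
        raise ValueError("combined saturation gaps cover >= 50% of the session")

    out = trace.samples.copy()
    keep = ~flagged
    t = trace.times
    edge = np.zeros(n, dtype=bool)
    # edge-touching runs: hold nearest intact value instead of extrapolating
    for start, stop in intervals:
        if start == 0 or stop == n:
            log.warning(
                "saturation interval [%d, %d) touches the signal edge; "
                "holding nearest value instead of extrapolating",
                start, stop,
            )
            edge[start:stop] = True
            if start == 0 and stop < n:
                out[start:stop] = out[stop]
            elif stop == n and start > 0:
                out[start:stop] = out[start - 1]
    interior = flagged & ~edge
    if interior.any():
        spline = CubicSpline(t[keep], trace.samples[keep])
        out[interior] = spline(t[interior])
    mask = trace.saturation_mask | flagged
    return replace(trace, samples=out, saturation_mask=mask)


def resample_to_ms(trace: RespirationTrace) -> RespirationTrace:
    """Linear resampling onto a 1 ms grid spanning the same time range."""
    if trace.rate > 1000:
        raise ValueError("resample_to_ms expects an input rate <= 1000 Hz")
    t = trace.times
    n_ms = int(round((t[-1] - t[0]) * 1000.0)) + 1
    new_t = t[0] + np.arange(n_ms) / 1000.0
    samples = np.interp(new_t, t, trace.samples)
    mask = np.interp(new_t, t, trace.saturation_mask.astype(float)) > 0.5
    return RespirationTrace(
        samples=samples, rate=1000.0, origin=trace.origin, saturation_mask=mask
    )


def align_to_session(trace: RespirationTrace, timeline) -> RespirationTrace:
    """Align the belt signal to the session clock by its *end*.

    The belt recording stops with the scanner, so the last sample maps to
    the end of the session: ``origin = session_duration - trace_duration``.
    """
    origin = float(timeline.session_duration) - trace.duration
    return replace(trace, origin=origin)


def detect_peaks(
    trace: RespirationTrace,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    min_prominence: Optional[float] = None,
) -> list[RespPeak]:
    """Extract respiration maxima as prominent local peaks.

    Defaults: peaks at least 1 s apart (shortest plausible breath) with
    prominence at least 10% of the 5th-95th percentile amplitude range.
    """
    x = trace.samples
    if min_prominence is None:
        q5, q95 = np.percentile(x, [5, 95])
        min_prominence = DEFAULT_PROMINENCE_FRAC * float(q95 - q5)
        log.debug("detect_peaks: default prominence %.4g a.u.", min_prominence)
    distance = max(1, int(round(min_separation * trace.rate)))
    idx, _ = find_peaks(x, prominence=min_prominence, distance=distance)
    t = trace.times
    return [
        RespPeak(time=float(t[i]), amplitude=float(x[i]), label=PeakLabel.UNLABELLED)
        for i in idx
    ]


def preprocess(
    trace: RespirationTrace,
    timeline=None,
    window_bins: int = DEFAULT_WINDOW_BINS,
    deriv_tol: Optional[float] = None,
    min_run: int = DEFAULT_MIN_RUN,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    min_prominence: Optional[float] = None,
) -> tuple[RespirationTrace, list[RespPeak], list[tuple[int, int]]]:
    """Full repair chain: smooth -> flag -> spline-repair -> resample ->
    align -> detect peaks.

    Returns the repaired millisecond-resolution trace, the detected peaks
    (session clock if a timeline is given), and the flagged sample
    intervals of the *input* trace.
    """
    smoothed = moving_average(trace, window_bins)
    intervals = detect_saturation(
        smoothed, deriv_tol=deriv_tol, min_run=min_run, expand_bins=window_bins // 2
    )
    repaired = interpolate_gaps(trace, intervals)
    resampled = resample_to_ms(repaired)
    if timeline is not None:
        resampled = align_to_session(resampled, timeline)
    peaks = detect_peaks(
        resampled, min_separation=min_separation, min_prominence=min_prominence
    )
    log.info(
        "preprocess: %d saturated intervals repaired, %d peaks detected",
        len(intervals), len(peaks),
    )
    return resampled, peaks, intervals
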