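"""Inter-Pausal Unit (IPU) segmentation from an RMS amplitude envelope.

An IPU is a stretch of continuous speech bounded by silences lasting longer
than 200 ms; it is the basic unit of conversational timing used throughout
this package.  Segmentation follows the classic recipe: compute a framewise
root-mean-square envelope of the (denoised) audio, derive a speaker-specific
amplitude threshold as a fraction of the mean RMS, classify frames as
speech/silence, merge short silences, and discard very short speech runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

PARTICIPANT = "participant"
INTERLOCUTOR = "interlocutor"

#: silences no longer than this merge into the surrounding speech (seconds);
#: the IPU definition splits only on pauses *longer* than 200 ms
DEFAULT_MIN_PAUSE = 0.2
#: speech runs shorter than this are treated as click artifacts (seconds)
DEFAULT_MIN_IPU = 0.1
DEFAULT_FRAME = 0.025
DEFAULT_HOP = 0.010

_EPS = 1e-9


@dataclass
class IPU:
    """One inter-pausal unit on some time axis (block-local or session)."""

    onset: float
    offset: float
    speaker: str = PARTICIPANT
    trial_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"IPU offset must exceed onset (got [{self.onset}, {self.offset}])"
            )
        if self.speaker not in (PARTICIPANT, INTERLOCUTOR):
            raise ValueError(f"unknown speaker {self.speaker!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Envelope:
    """Framewise RMS amplitude on a uniform hop grid (times are frame centers)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("envelope times and values must have equal length")

    @property
    def hop(self) -> float:
        if len(self.times) < 2:
            raise ValueError("envelope with < 2 frames has no hop")
        return float(np.median(np.diff(self.times)))


def rms_envelope(
    samples: np.ndarray,
    rate: float,
    frame: float = DEFAULT_FRAME,
    hop: float = DEFAULT_HOP,
) -> Envelope:
    """Framewise root-mean-square envelope.

    Parameters
    ----------
    samples : audio samples (mono).
    rate : sampling rate in Hz.
    frame : analysis window length in seconds (>= hop).
    hop : frame step in seconds.
    """
    if not frame >= hop > 0:
        raise ValueError("require frame >= hop > 0")
    x = np.asarray(samples, dtype=float)
    frame_len = max(1, int(round(frame * rate)))
    hop_len = max(1, int(round(hop * rate)))
    if len(x) < frame_len:
        raise ValueError(
            f"audio ({len(x)} samples) shorter than one frame ({frame_len} samples)"
        )
    n_frames = 1 + (len(x) - frame_len) // hop_len
    starts = np.arange(n_frames) * hop_len
    windows = np.lib.stride_tricks.sliding_window_view(x, frame_len)[starts]
    values = np.sqrt(np.mean(windows**2, axis=1))
    times = (starts + frame_len / 2.0) / rate
    return Envelope(times=times, values=values)


def threshold_from_rms(envelope: Envelope, coefficient: float) -> float:
    """Speech/silence amplitude threshold: ``coefficient * mean(envelope)``.

    Coefficients are speaker-specific; values outside [0.20, 0.95] are
    accepted but flagged, as they fall outside the usual working range.
    """
    if len(envelope.values) == 0:
        raise ValueError("empty envelope")
    if not 0.20 <= coefficient <= 0.95:
        log.warning(
            "RMS coefficient %.3f outside the usual range [0.20, 0.95]", coefficient
        )
    mean = float(np.mean(envelope.values))
    if mean == 0.0:
        log.warning("zero envelope: threshold 0 classifies everything as speech")
    return coefficient * mean


def segment_ipus(
    envelope: Envelope,
    threshold: float,
    min_pause: float = DEFAULT_MIN_PAUSE,
    min_ipu: float = DEFAULT_MIN_IPU,
    speaker: str = PARTICIPANT,
    trial_id: Optional[int] = None,
) -> list[IPU]:
    """Segment an envelope into IPUs.

    Frames with amplitude >= ``threshold`` are speech.  Sub-threshold runs
    whose duration does not exceed ``min_pause`` merge into the surrounding
    speech (the pause rule is strict: a silence splits speech only if it
    lasts *longer* than ``min_pause``).  Speech runs shorter than
    ``min_ipu`` after merging are dropped.  Boundaries are reported at
    frame-edge resolution (frame center +/- hop/2).
    """
    values = envelope.values
    if len(values) == 0:
        return []
    if len(values) == 1:
        hop = DEFAULT_HOP
    else:
        hop = envelope.hop
    speech = values >= threshold
    if not speech.any():
        return []

    # run-length encode, merge short silences, drop short speech
    runs = _runs(speech)
    merged: list[tuple[int, int]] = []  # speech runs as [start, stop) frames
    for is_speech, start, stop in runs:
        if is_speech:
            if merged and _gap_mergeable(merged[-1][1], start, hop, min_pause):
                merged[-1] = (merged[-1][0], stop)
            else:
                merged.append((start, stop))
    ipus: list[IPU] = []
    for start, stop in merged:
        onset = envelope.times[start] - hop / 2.0
        offset = envelope.times[stop - 1] + hop / 2.0
        if offset - onset < min_ipu - _EPS:
            continue
        ipus.append(IPU(onset=onset, offset=offset, speaker=speaker, trial_id=trial_id))
    return ipus


def _gap_mergeable(prev_stop: int, next_start: int, hop: float, min_pause: float) -> bool:
    gap = (next_start - prev_stop) * hop
    return gap <= min_pause + _EPS


def _runs(mask: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean mask as (value, start, stop) triples."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(mask)]))
    return [
        (bool(mask[bounds[i]]), int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
    ]


def tune_coefficient(
    envelope: Envelope,
    reference_ipus: Sequence[IPU],
    grid: Optional[Sequence[float]] = None,
    tolerance: float = 0.05,
    **segment_kwargs,
) -> float:
    """Grid-search the RMS coefficient against annotated IPUs (extension).

    Convenience helper, not part of the core procedure: scores each
    candidate coefficient by boundary F1 (onsets/offsets matched within
    ``tolerance`` seconds) and returns the best one.
    """
    if grid is None:
        grid = np.round(np.arange(0.20, 0.951, 0.05), 2)
    ref = np.array(
        [b for ipu in reference_ipus for b in (ipu.onset, ipu.offset)], dtype=float
    )
    best_coeff, best_f1 = float(grid[0]), -1.0
    for coeff in grid:
        thr = threshold_from_rms(envelope, float(coeff))
        got = segment_ipus(envelope, thr, **segment_kwargs)
        hyp = np.array([b for ipu in got for b in (ipu.onset, ipu.offset)], dtype=float)
        f1 = _boundary_f1(ref, hyp, tolerance)
        if f1 > best_f1:
            best_coeff, best_f1 = float(coeff), f1
    return best_coeff


def _boundary_f1(ref: np.ndarray, hyp: np.ndarray, tol: float) -> float:
    if len(ref) == 0 or len(hyp) == 0:
        return 0.0
    hits = sum(1 for r in ref if np.min(np.abs(hyp - r)) <= tol)
    precision = sum(1 for h in hyp if np.min(np.abs(ref - h)) <= tol) / len(hyp)
    recall = hits / len(ref)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
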