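"""Link respiration maxima to speech onsets.

Every respiration maximum that is the temporally closest maximum (in
absolute value) to some participant IPU onset is labelled Resp+; all other
maxima are Resp-.  The per-IPU lag is Delta-t = peak_time - ipu_onset
(negative when the breath maximum precedes speech onset).  The labelled
maxima are exported as zero-duration events suitable as GLM regressor
inputs, which is where this pipeline's scope ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ipu_segment import IPU, PARTICIPANT
from .resp_preproc import PeakLabel, RespPeak

log = logging.getLogger(__name__)


@dataclass
class DeltaTRecord:
    """Per-IPU lag between its onset and the closest respiration maximum."""

    ipu_id: int
    peak_time: float
    ipu_onset: float
    delta_t: float
    outlier: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")


def ipus_to_session_clock(
    ipus: Sequence[IPU],
    block_onsets: Union[Mapping[int, float], Sequence[float]],
) -> list[IPU]:
    """Shift block-relative IPUs onto the session clock.

    Each IPU's ``trial_id`` indexes into ``block_onsets`` (a mapping or a
    sequence ordered by block).  An IPU extending past the next block's
    onset is kept, with a warning.
    """
    if not isinstance(block_onsets, Mapping):
        block_onsets = {i: float(v) for i, v in enumerate(block_onsets)}
    ordered = sorted(block_onsets.items())
    next_onset = {k: ordered[i + 1][1] if i + 1 < len(ordered) else np.inf
                  for i, (k, _) in enumerate(ordered)}
    shifted = []
    for ipu in ipus:
        if ipu.trial_id is None or ipu.trial_id not in block_onsets:
            raise ValueError(f"IPU at {ipu.onset:.3f} has no known block onset")
        onset0 = block_onsets[ipu.trial_id]
        new = replace(ipu, onset=ipu.onset + onset0, offset=ipu.offset + onset0)
        if new.offset > next_onset[ipu.trial_id]:
            log.warning(
                "IPU [%.3f, %.3f] extends past the next block onset; kept",
                new.onset, new.offset,
            )
        shifted.append(new)
    return sorted(shifted, key=lambda i: (i.onset, i.offset))


def classify_peaks(
    peaks: Sequence[RespPeak],
    participant_ipu_onsets: Sequence[float],
) -> tuple[list[RespPeak], list[DeltaTRecord]]:
    """Label maxima Resp+/Resp- by nearest-neighbour association.

    For each participant IPU onset, the maximum minimizing
    ``|peak_time - onset|`` is Resp+ and linked to that IPU; all never-linked
    maxima are Resp-.  There is no maximum matching window: the nearest peak
    is Resp+ however far away (extreme lags are handled downstream by the
    MAD filter).  A peak that is nearest to several onsets appears once in
    the event list but contributes one Delta-t record per IPU.  Two peaks
    exactly equidistant from an onset tie toward the earlier peak
    (inhalation precedes speech physiologically).
    """
    if len(peaks) == 0:
        raise ValueError("need at least one respiration maximum")
    times = np.array([p.time for p in peaks])
    if np.any(np.diff(times) <= 0):
        raise ValueError("peaks must be sorted and strictly increasing in time")

    linked: dict[int, int] = {}  # peak index -> first linking IPU id
    records: list[DeltaTRecord] = []
    n_ties = 0
    for ipu_id, onset in enumerate(participant_ipu_onsets):
        j = int(np.searchsorted(times, onset))
        left = j - 1
        right = j if j < len(times) else len(times) - 1
        if left < 0:
            best = right
        else:
            d_left = abs(times[left] - onset)
            d_right = abs(times[right] - onset)
            if d_left == d_right and left != right:
                n_ties += 1
            best = left if d_left <= d_right else right  # tie -> earlier peak
        linked.setdefault(best, ipu_id)
        records.append(
            DeltaTRecord(
                ipu_id=ipu_id,
                peak_time=float(times[best]),
                ipu_onset=float(onset),
                delta_t=float(times[best] - onset),
            )
        )
    if n_ties:
        log.info("classify_peaks: %d equidistant ties broken toward the earlier peak", n_ties)

    labelled = [
        replace(
            p,
            label=PeakLabel.RESP_PLUS if i in linked else PeakLabel.RESP_MINUS,
            ipu_id=linked.get(i),
        )
        for i, p in enumerate(peaks)
    ]
    n_plus = len(linked)
    log.info(
        "classify_peaks: %d Resp+ events from %d IPUs (%d peaks total, %d Delta-t records)",
        n_plus, len(participant_ipu_onsets), len(peaks), len(records),
    )
    return labelled, records


def export_glm_events(
    peaks: Sequence[RespPeak],
    ipus: Sequence[IPU],
) -> pd.DataFrame:
    """Build the BIDS-style events table: zero-duration resp_plus/resp_minus
    rows plus ipu_participant/ipu_interlocutor rows with true durations."""
    rows = []
    for p in peaks:
        if p.label == PeakLabel.UNLABELLED:
            raise ValueError("peaks must be classified before export")
        rows.append(
            {
                "onset": p.time,
                "duration": 0.0,
                "trial_type": p.label.value,
                "trial_id": -1 if p.ipu_id is None else p.ipu_id,
            }
        )
    for k, ipu in enumerate(ipus):
        rows.append(
            {
                "onset": ipu.onset,
                "duration": ipu.duration,
                "trial_type": f"ipu_{ipu.speaker}",
                "trial_id": k if ipu.trial_id is None else ipu.trial_id,
            }
        )
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "trial_id"])
    return df.sort_values("onset", kind="stable", ignore_index=True)


def records_to_frame(records: Sequence[DeltaTRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ipu_id": r.ipu_id,
                "peak_time": r.peak_time,
                "ipu_onset": r.ipu_onset,
                "delta_t": r.delta_t,
                "outlier": int(r.outlier),
            }
            for r in records
        ],
        columns=["ipu_id", "peak_time", "ipu_onset", "delta_t", "outlier"],
    )


def frame_to_records(df: pd.DataFrame) -> list[DeltaTRecord]:
    return [
        DeltaTRecord(
            ipu_id=int(r.ipu_id),
            peak_time=float(r.peak_time),
            ipu_onset=float(r.ipu_onset),
            delta_t=float(r.delta_t),
            outlier=bool(r.outlier),
        )
        for r in df.itertuples(index=False)
    ]
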