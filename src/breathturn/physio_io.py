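"""On-disk formats and session-clock bookkeeping.

All times are seconds on the session clock (origin = start of the fMRI
session).  Belt traces travel as 2-column TSV (time_s, amplitude); events
follow the BIDS events dialect (tab-separated ``onset  duration
trial_type``); IPU annotations are read from TextGrid interval tiers or
events TSV; ground truth and results are JSON; configuration is YAML.
Everything is UTF-8 text with a decimal point.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ipu_segment import INTERLOCUTOR, IPU, PARTICIPANT
from .resp_preproc import RespirationTrace

log = logging.getLogger(__name__)

TRIAL_TYPES = ("resp_plus", "resp_minus", "ipu_participant", "ipu_interlocutor")

#: maximum tolerated inconsistency between n_volumes*tr and session_duration
CLOCK_TOL = 1e-3  # 1 ms


@dataclass
class SessionTimeline:
    """fMRI session clock: duration, volume count, TR, and block onsets."""

    session_duration: float
    n_volumes: Optional[int] = None
    tr: Optional[float] = None
    block_onsets: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_volumes is not None and self.tr is not None:
            expected = self.n_volumes * self.tr
            if abs(expected - self.session_duration) > CLOCK_TOL:
                raise ValueError(
                    f"session_duration {self.session_duration} inconsistent with "
                    f"n_volumes*tr = {expected} (> 1 ms apart)"
                )
        onsets = list(self.block_onsets)
        if onsets != sorted(onsets):
            raise ValueError("block onsets must be sorted")
        for onset in onsets:
            if not 0 <= onset <= self.session_duration:
                raise ValueError(f"block onset {onset} outside [0, session_duration]")
        self.block_onsets = [float(o) for o in onsets]


# ---------------------------------------------------------------------------
# belt traces


def read_belt_tsv(path: Union[str, Path], rate: Optional[float] = None) -> RespirationTrace:
    """Read a belt trace from TSV/CSV.

    Two numeric columns are interpreted as (time_s, amplitude); a single
    column requires a declared ``rate``.  Sampling must be uniform (max
    jitter below half a sample period), otherwise the trace is resampled
    onto a uniform grid with a warning.
    """
    path = Path(path)
    first = ""
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    kwargs = {} if sep == r"\s+" else {"float_precision": "round_trip"}
    df = pd.read_csv(path, sep=sep, comment="#", **kwargs)
    if df.empty:
        raise ValueError(f"{path}: empty belt file")
    _check_finite(df, path)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        x = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError(f"{path}: need at least two samples")
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: non-monotone time at row {row}")
        period = float(np.median(dt))
        jitter = float(np.max(np.abs(dt - period)))
        if jitter >= period / 2:
            log.warning(
                "%s: sampling jitter %.3g s exceeds half a period; resampling "
                "onto a uniform grid", path, jitter,
            )
            n = int(round((t[-1] - t[0]) / period)) + 1
            grid = t[0] + np.arange(n) * period
            x = np.interp(grid, t, x)
            t = grid
        inferred = (len(t) - 1) / (t[-1] - t[0])
        return RespirationTrace(samples=x, rate=float(inferred), origin=float(t[0]))
    if rate is None:
        raise ValueError(f"{path}: single-column belt file requires a declared rate")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    return RespirationTrace(samples=x, rate=float(rate), origin=0.0)


def write_belt_tsv(path: Union[str, Path], trace: RespirationTrace) -> None:
    """Write a belt trace as 2-column TSV; amplitudes keep full float precision."""
    path = Path(path)
    t = trace.times
    with path.open("w", encoding="utf-8") as fh:
        fh.write("time_s\tamplitude\n")
        for ti, xi in zip(t, trace.samples):
            fh.write(f"{ti:.6f}\t{float(xi)!r}\n")


# ---------------------------------------------------------------------------
# session logs


def read_session_log(path: Union[str, Path]) -> SessionTimeline:
    """Parse a plain-text session log of ``key<TAB>value`` lines.

    Recognized keys: ``n_volumes``, ``tr``, ``session_duration``,
    ``block_onset`` (repeated).  Either ``session_duration`` or the pair
    (``n_volumes``, ``tr``) must be present; if both are given they must
    agree to 1 ms.
    """
    path = Path(path)
    n_volumes = tr = duration = None
    onsets: list[float] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t ]+", line, maxsplit=1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'key<TAB>value'")
        key, value = parts[0].lower(), parts[1].strip()
        if key == "n_volumes":
            n_volumes = int(value)
        elif key == "tr":
            tr = float(value)
        elif key == "session_duration":
            duration = float(value)
        elif key == "block_onset":
            onsets.append(float(value))
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if duration is None:
        if n_volumes is None or tr is None:
            raise ValueError(
                f"{path}: need session_duration or both n_volumes and tr"
            )
        duration = n_volumes * tr
    return SessionTimeline(
        session_duration=float(duration),
        n_volumes=n_volumes,
        tr=tr,
        block_onsets=sorted(onsets),
    )


def write_session_log(path: Union[str, Path], timeline: SessionTimeline) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if timeline.n_volumes is not None:
            fh.write(f"n_volumes\t{timeline.n_volumes}\n")
        if timeline.tr is not None:
            fh.write(f"tr\t{timeline.tr:.6f}\n")
        fh.write(f"session_duration\t{timeline.session_duration:.6f}\n")
        for onset in timeline.block_onsets:
            fh.write(f"block_onset\t{onset:.6f}\n")


# ---------------------------------------------------------------------------
# events tables (BIDS dialect)


def validate_events(df: pd.DataFrame, path: Union[str, Path, None] = None) -> None:
    where = f"{path}: " if path else ""
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{where}missing events column {col!r}")
    _check_finite(df[["onset", "duration"]], path or "<events>")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError(f"{where}event onsets must be sorted")
    if np.any(df["duration"].to_numpy(dtype=float) < 0):
        raise ValueError(f"{where}event durations must be >= 0")
    resp = df["trial_type"].astype(str).str.startswith("resp")
    if np.any(df.loc[resp, "duration"].to_numpy(dtype=float) != 0.0):
        raise ValueError(f"{where}resp_* events must have duration exactly 0")


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    validate_events(df, path)
    return df


def write_events(path: Union[str, Path], events: pd.DataFrame) -> None:
    validate_events(events)
    cols = ["onset", "duration", "trial_type"] + [
        c for c in events.columns if c not in ("onset", "duration", "trial_type")
    ]
    events = events[cols]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in events.itertuples(index=False):
            cells = []
            for col, val in zip(cols, row):
                if col in ("onset", "duration") or isinstance(val, float):
                    cells.append("n/a" if pd.isna(val) else f"{val:.6f}")
                else:
                    cells.append("n/a" if pd.isna(val) else str(val))
            fh.write("\t".join(cells) + "\n")


def ipus_to_events(ipus: Sequence[IPU]) -> pd.DataFrame:
    rows = [
        {
            "onset": ipu.onset,
            "duration": ipu.duration,
            "trial_type": f"ipu_{ipu.speaker}",
            "trial_id": -1 if ipu.trial_id is None else ipu.trial_id,
        }
        for ipu in sorted(ipus, key=lambda i: i.onset)
    ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "trial_id"])


def events_to_ipus(df: pd.DataFrame) -> list[IPU]:
    ipus = []
    for row in df.itertuples(index=False):
        if not str(row.trial_type).startswith("ipu_"):
            continue
        speaker = str(row.trial_type)[len("ipu_"):]
        trial_id = getattr(row, "trial_id", None)
        if trial_id is not None:
            trial_id = None if int(trial_id) < 0 else int(trial_id)
        ipus.append(
            IPU(
                onset=float(row.onset),
                offset=float(row.onset) + float(row.duration),
                speaker=speaker,
                trial_id=trial_id,
            )
        )
    return ipus


# ---------------------------------------------------------------------------
# TextGrid interval tiers (minimal long-format reader/writer)


def read_ipu_annotations(path: Union[str, Path], **kwargs) -> list[IPU]:
    """Read IPUs from a TextGrid interval tier or an events TSV.

    TextGrid intervals with non-empty labels become IPUs; empty labels are
    silences.  Overlapping intervals within one tier are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".textgrid":
        return _read_textgrid_ipus(path, **kwargs)
    return events_to_ipus(read_events(path))


def _read_textgrid_ipus(
    path: Path, tier: Optional[str] = None, speaker: str = PARTICIPANT
) -> list[IPU]:
    text = path.read_text(encoding="utf-8")
    tiers = _parse_textgrid(text, path)
    if tier is not None:
        if tier not in tiers:
            raise ValueError(f"{path}: no tier named {tier!r}")
        intervals = tiers[tier]
    else:
        intervals = next(iter(tiers.values()))
    prev_end = -np.inf
    ipus = []
    for xmin, xmax, label in intervals:
        if xmin < prev_end - 1e-9:
            raise ValueError(f"{path}: overlapping intervals in tier")
        prev_end = xmax
        if label.strip():
            ipus.append(IPU(onset=xmin, offset=xmax, speaker=speaker))
    return ipus


def _parse_textgrid(text: str, path: Path) -> dict[str, list[tuple[float, float, str]]]:
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    tier_chunks = re.split(r"item \[\d+\]:", text)[1:]
    if not tier_chunks:
        raise ValueError(f"{path}: no tiers found (expected long-format TextGrid)")
    for chunk in tier_chunks:
        name_m = re.search(r'name\s*=\s*"([^"]*)"', chunk)
        name = name_m.group(1) if name_m else f"tier{len(tiers)}"
        intervals = []
        for m in re.finditer(
            r"intervals \[\d+\]:\s*xmin\s*=\s*([-\d.eE+]+)\s*"
            r"xmax\s*=\s*([-\d.eE+]+)\s*text\s*=\s*\"((?:[^\"]|\"\")*)\"",
            chunk,
        ):
            xmin, xmax = float(m.group(1)), float(m.group(2))
            label = m.group(3).replace('""', '"')
            intervals.append((xmin, xmax, label))
        tiers[name] = intervals
    return tiers


def write_textgrid(
    path: Union[str, Path],
    ipus: Sequence[IPU],
    tier_name: str = "ipu",
    xmax: Optional[float] = None,
) -> None:
    """Write IPUs as one long-format TextGrid interval tier.

    Gaps between IPUs become empty-label (silence) intervals.
    """
    ipus = sorted(ipus, key=lambda i: i.onset)
    if xmax is None:
        xmax = ipus[-1].offset if ipus else 1.0
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for ipu in ipus:
        if ipu.onset > cursor + 1e-9:
            intervals.append((cursor, ipu.onset, ""))
        intervals.append((ipu.onset, ipu.offset, "speech"))
        cursor = ipu.offset
    if xmax > cursor + 1e-9:
        intervals.append((cursor, xmax, ""))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (xmin, xm, label) in enumerate(intervals, 1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {xmin:.6f}",
            f"            xmax = {xm:.6f}",
            f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# peak tables


def write_peaks_tsv(path: Union[str, Path], peaks) -> None:
    """Write detected respiration maxima as TSV (time_s, amplitude, label, ipu_id)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("time_s\tamplitude\tlabel\tipu_id\n")
        for p in peaks:
            label = p.label.value if hasattr(p.label, "value") else str(p.label)
            ipu_id = -1 if p.ipu_id is None else int(p.ipu_id)
            fh.write(f"{p.time:.6f}\t{float(p.amplitude)!r}\t{label}\t{ipu_id}\n")


def read_peaks_tsv(path: Union[str, Path]):
    from .resp_preproc import PeakLabel, RespPeak

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_finite(df[["time_s", "amplitude"]], path)
    return [
        RespPeak(
            time=float(r.time_s),
            amplitude=float(r.amplitude),
            label=PeakLabel(str(r.label)),
            ipu_id=None if int(r.ipu_id) < 0 else int(r.ipu_id),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# helpers


def _check_finite(df: pd.DataFrame, path) -> None:
    numeric = df.select_dtypes(include=[np.number])
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(f"{path}: non-finite value at data row {row}")


def write_json(path: Union[str, Path], payload) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path: Union[str, Path]):
    return json.loads(Path(path).read_text(encoding="utf-8"))
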