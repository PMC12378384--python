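"""End-to-end orchestration: synthesize -> preprocess -> segment -> align ->
stats, with YAML configuration, provenance, and reproducibility controls.

Stage boundaries are exactly the on-disk formats of :mod:`.physio_io`, so
any stage can be re-run in isolation or replaced by external tooling; fixed
seeds reproduce byte-identical outputs.  No stage mutates its inputs on
disk.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from importlib import metadata
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import event_align, ipu_segment, physio_io, resp_preproc, synthio, timing_stats
from .ipu_segment import INTERLOCUTOR, PARTICIPANT

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "segment", "align", "stats")

try:
    __version__ = metadata.version("breathturn")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


def default_config() -> dict:
    """Full run configuration with every module default made explicit.

    The session layout mirrors the acquisition this pipeline targets: 385
    volumes at TR 1.205 s (463.925 s), six one-minute conversation blocks
    alternating human and robot interlocutors.
    """
    return {
        "seed": 0,
        "sampling_rate": 200.0,
        "session": {
            "n_volumes": 385,
            "tr": 1.205,
            "n_blocks": 6,
            "block_duration": 60.0,
            "first_block_onset": 20.0,
            "block_spacing": 72.0,
            "conditions": ["human", "robot", "human", "robot", "human", "robot"],
        },
        "conversation": {
            "mean_turn": 4.0,
            "mean_gap": 1.5,
            "min_turn": 1.0,
            "min_gap": 0.25,
            "turn_shape": 4.0,
            "gap_shape": 2.0,
            "p_switch": 0.75,
        },
        "breath": {
            "inhale_dur_range": [0.2, 0.5],
            "exhale_dur_range": [1.5, 4.0],
            "amplitude_range": [0.5, 1.0],
            "deep_fraction": 0.10,
            "deep_amplitude_range": [1.2, 1.6],
            "baseline_drift_sd": 0.005,
            "noise_sd": 0.01,
        },
        "lag": {
            "family": "shifted_negative_gamma",
            "mode": -0.200,
            "spread": 0.10,
            "shape": 3.0,
        },
        "coupling": {
            "coupled_fraction": synthio.DEFAULT_COUPLED_FRACTION,
            "onset_guard": synthio.DEFAULT_ONSET_GUARD,
        },
        "saturation": {"enabled": True, "rail_low": -0.2, "rail_high": 1.1},
        "envelope": {
            "frame": 0.025,
            "hop": 0.010,
            "speech_level": 1.0,
            "noise_level": 0.05,
        },
        "preproc": {
            "window_bins": 50,
            "min_run": 10,
            "deriv_tol": None,
            "min_separation": 1.0,
            "min_prominence": None,
        },
        "segment": {"coefficient": 0.5, "min_pause": 0.2, "min_ipu": 0.1},
        "stats": {"mad_k": 3.0, "mad_scale": "normal", "bandwidth": None},
    }


def load_config(path: Union[str, Path]) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    return merge_config(overrides)


def merge_config(overrides: dict) -> dict:
    config = default_config()
    for section, value in overrides.items():
        if isinstance(value, dict) and isinstance(config.get(section), dict):
            config[section].update(value)
        else:
            config[section] = value
    return config


def save_config(path: Union[str, Path], config: dict) -> None:
    Path(path).write_text(
        yaml.safe_dump(config, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _timeline(config: dict) -> physio_io.SessionTimeline:
    s = config["session"]
    onsets = [
        s["first_block_onset"] + k * s["block_spacing"] for k in range(s["n_blocks"])
    ]
    return physio_io.SessionTimeline(
        session_duration=s["n_volumes"] * s["tr"],
        n_volumes=s["n_volumes"],
        tr=s["tr"],
        block_onsets=onsets,
    )


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """One child stream per generator call, derived from the session seed."""
    return np.random.SeedSequence(seed).spawn(n)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path) -> None:
    s = config["session"]
    timeline = _timeline(config)
    physio_io.write_session_log(outdir / "session.tsv", timeline)

    n_blocks = s["n_blocks"]
    kids = _child_seeds(config["seed"], 2 * n_blocks + 1)
    turn_params = synthio.TurnParams(**config["conversation"])

    all_ipus = []
    for k, onset in enumerate(timeline.block_onsets):
        block_ipus = synthio.generate_conversation(
            s["block_duration"], turn_params, seed=kids[k]
        )
        for ipu in block_ipus:
            ipu.trial_id = k
        all_ipus.extend(
            event_align.ipus_to_session_clock(block_ipus, {k: onset})
        )
        env = synthio.render_rms_envelope(
            [i for i in block_ipus if i.speaker == PARTICIPANT],
            duration=s["block_duration"],
            seed=kids[n_blocks + k],
            **config["envelope"],
        )
        _write_envelope(outdir / f"envelope_block{k}.tsv", env)
    all_ipus.sort(key=lambda i: i.onset)
    physio_io.write_events(outdir / "ipus_true.tsv", physio_io.ipus_to_events(all_ipus))

    breath = dict(config["breath"])
    for key in ("inhale_dur_range", "exhale_dur_range", "amplitude_range",
                "deep_amplitude_range"):
        if key in breath:
            breath[key] = tuple(breath[key])
    bp = synthio.BreathCycleParams(**breath)
    lm = synthio.LagModel(**config["lag"])
    trace, truth = synthio.generate_respiration(
        all_ipus,
        breath_params=bp,
        lag_model=lm,
        coupled_fraction=config["coupling"]["coupled_fraction"],
        onset_guard=config["coupling"]["onset_guard"],
        sampling_rate=config["sampling_rate"],
        seed=kids[2 * n_blocks],
        duration=timeline.session_duration,
    )
    sat = config["saturation"]
    if sat["enabled"]:
        trace, intervals = synthio.apply_saturation(
            trace, sat["rail_low"], sat["rail_high"]
        )
        truth.saturated_intervals = [
            (start / trace.rate, stop / trace.rate) for start, stop in intervals
        ]
    physio_io.write_belt_tsv(outdir / "belt.tsv", trace)
    physio_io.write_json(outdir / "truth.json", truth.to_dict())
    log.info("simulate: %d IPUs, %d true maxima, %d saturated runs",
             len(all_ipus), len(truth.true_peak_times), len(truth.saturated_intervals))


def stage_preprocess(config: dict, outdir: Path) -> None:
    trace = physio_io.read_belt_tsv(outdir / "belt.tsv")
    timeline = physio_io.read_session_log(outdir / "session.tsv")
    _, peaks, intervals = resp_preproc.preprocess(trace, timeline, **config["preproc"])
    physio_io.write_peaks_tsv(outdir / "peaks.tsv", peaks)
    log.info("preprocess: %d peaks, %d repaired intervals", len(peaks), len(intervals))


def stage_segment(config: dict, outdir: Path) -> None:
    timeline = physio_io.read_session_log(outdir / "session.tsv")
    seg = config["segment"]
    detected = []
    for k, onset in enumerate(timeline.block_onsets):
        env = _read_envelope(outdir / f"envelope_block{k}.tsv")
        thr = ipu_segment.threshold_from_rms(env, seg["coefficient"])
        block_ipus = ipu_segment.segment_ipus(
            env, thr, min_pause=seg["min_pause"], min_ipu=seg["min_ipu"],
            speaker=PARTICIPANT, trial_id=k,
        )
        detected.extend(event_align.ipus_to_session_clock(block_ipus, {k: onset}))
    detected.sort(key=lambda i: i.onset)
    physio_io.write_events(
        outdir / "ipus_detected.tsv", physio_io.ipus_to_events(detected)
    )
    log.info("segment: %d participant IPUs detected", len(detected))


def stage_align(config: dict, outdir: Path) -> None:
    peaks = physio_io.read_peaks_tsv(outdir / "peaks.tsv")
    participant = physio_io.events_to_ipus(
        physio_io.read_events(outdir / "ipus_detected.tsv")
    )
    truth_ipus = physio_io.events_to_ipus(
        physio_io.read_events(outdir / "ipus_true.tsv")
    )
    interlocutor = [i for i in truth_ipus if i.speaker == INTERLOCUTOR]

    onsets = [i.onset for i in participant]
    labelled, records = event_align.classify_peaks(peaks, onsets)
    physio_io.write_peaks_tsv(outdir / "peaks_labelled.tsv", labelled)
    events = event_align.export_glm_events(labelled, participant + interlocutor)
    physio_io.write_events(outdir / "events.tsv", events)

    conditions = config["session"]["conditions"]
    df = event_align.records_to_frame(records)
    df["condition"] = [
        conditions[participant[r.ipu_id].trial_id]
        if participant[r.ipu_id].trial_id is not None else "unknown"
        for r in records
    ]
    df.to_csv(outdir / "deltas.tsv", sep="\t", index=False, float_format="%.6f")
    log.info("align: %d Delta-t records", len(records))


def stage_stats(config: dict, outdir: Path) -> None:
    df = pd.read_csv(outdir / "deltas.tsv", sep="\t")
    peaks = physio_io.read_peaks_tsv(outdir / "peaks_labelled.tsv")
    n_resp_plus = sum(1 for p in peaks if p.label == resp_preproc.PeakLabel.RESP_PLUS)
    by_condition = None
    if "condition" in df.columns and df["condition"].nunique() == 2:
        by_condition = {
            str(cond): grp["delta_t"].to_numpy()
            for cond, grp in df.groupby("condition")
        }
        if any(len(v) < 2 for v in by_condition.values()):
            by_condition = None
    st = config["stats"]
    summary, cdf = timing_stats.summarize(
        df["delta_t"].to_numpy(),
        mad_k=st["mad_k"],
        mad_scale=st["mad_scale"],
        bandwidth=st["bandwidth"],
        n_peaks=len(peaks),
        n_resp_plus=n_resp_plus,
        deltas_by_condition=by_condition,
    )
    kept, _ = timing_stats.remove_outliers_mad(
        df["delta_t"].to_numpy(), k=st["mad_k"], scale=st["mad_scale"]
    )
    flagged = df.copy()
    med = np.median(df["delta_t"])
    cutoff = st["mad_k"] * (
        timing_stats.MAD_NORMAL_SCALE if st["mad_scale"] == "normal" else 1.0
    ) * np.median(np.abs(df["delta_t"] - med))
    flagged["outlier"] = (np.abs(df["delta_t"] - med) > cutoff).astype(int)
    flagged.to_csv(outdir / "deltas_flagged.tsv", sep="\t", index=False,
                   float_format="%.6f")
    cdf.to_csv(outdir / "cdf.tsv", sep="\t", index=False, float_format="%.6f")
    payload = summary.to_dict()
    payload["provenance"] = {
        "config_sha256": config_hash(config),
        "seed": config["seed"],
        "software": f"breathturn {__version__}",
    }
    physio_io.write_json(outdir / "summary.json", payload)
    log.info("stats: mode %s, skewness %.3f, %.2f%% removed",
             "n/a" if summary.mode is None else f"{summary.mode:.4f} s",
             summary.skewness, summary.pct_removed)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "segment": stage_segment,
    "align": stage_align,
    "stats": stage_stats,
}


def run_session(
    config: dict,
    outdir: Union[str, Path],
    stages: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Run one session end to end (or a subset of stages) into ``outdir``.

    Re-running with the same config and seed reproduces byte-identical
    outputs.  A plain-text log of every applied default and warning is
    written alongside the results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    save_config(outdir / "config.yaml", config)

    handler = logging.FileHandler(outdir / "run.log", mode="a", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("breathturn")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            try:
                _STAGE_FUNCS[stage](config, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed in {outdir}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return {
        "events": outdir / "events.tsv",
        "deltas": outdir / "deltas.tsv",
        "summary": outdir / "summary.json",
        "log": outdir / "run.log",
    }


def make_cohort_configs(
    base_config: Optional[dict] = None,
    n_participants: int = 25,
    n_sessions: int = 4,
    base_seed: int = 0,
) -> list[dict]:
    """Per-session configs for a cohort; seeds are derived deterministically
    from ``base_seed`` and stay below 2**31."""
    base = copy.deepcopy(base_config) if base_config else default_config()
    configs = []
    for p in range(n_participants):
        for s in range(n_sessions):
            cfg = copy.deepcopy(base)
            cfg["seed"] = int((base_seed * 7919 + p * 101 + s) % (2**31))
            cfg["participant"] = p
            cfg["session_index"] = s
            configs.append(cfg)
    return configs


def run_cohort(
    configs: Sequence[dict],
    outdir: Union[str, Path],
) -> dict:
    """Run several sessions and pool their lag statistics.

    Pooling is reported at both aggregation levels: all Delta-t records
    pooled across sessions (IPU level) and the distribution of per-session
    mean lags (session level).
    """
    if len(configs) == 0:
        raise ValueError("need at least one session config")
    outdir = Path(outdir)
    all_deltas = []
    session_means = []
    summaries = []
    total_peaks = 0
    total_resp_plus = 0
    for i, cfg in enumerate(configs):
        sess_dir = outdir / f"sub-{cfg.get('participant', i):02d}_ses-{cfg.get('session_index', 0)}"
        run_session(cfg, sess_dir)
        df = pd.read_csv(sess_dir / "deltas.tsv", sep="\t")
        summary = physio_io.read_json(sess_dir / "summary.json")
        summaries.append(summary)
        st = cfg["stats"]
        kept, _ = timing_stats.remove_outliers_mad(
            df["delta_t"].to_numpy(), k=st["mad_k"], scale=st["mad_scale"]
        )
        all_deltas.append(df["delta_t"].to_numpy())  # pooled cleaning happens once
        session_means.append(float(np.mean(kept)))
        peaks = physio_io.read_peaks_tsv(sess_dir / "peaks_labelled.tsv")
        total_peaks += len(peaks)
        total_resp_plus += sum(
            1 for p in peaks if p.label == resp_preproc.PeakLabel.RESP_PLUS
        )
    pooled = np.concatenate(all_deltas)
    st = configs[0]["stats"]
    pooled_summary, pooled_cdf = timing_stats.summarize(
        pooled, mad_k=st["mad_k"], mad_scale=st["mad_scale"],
        bandwidth=st["bandwidth"], n_peaks=total_peaks,
        n_resp_plus=total_resp_plus,
    )
    means = np.asarray(session_means)
    payload = {
        "ipu_level": pooled_summary.to_dict(),
        "session_level": {
            "n_sessions": len(configs),
            "mean_of_means": float(means.mean()),
            "sd_of_means": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
            "session_means": [float(m) for m in means],
        },
        "n_peaks": total_peaks,
        "n_resp_plus": total_resp_plus,
        "provenance": {
            "n_sessions": len(configs),
            "config_sha256_first": config_hash(configs[0]),
            "software": f"breathturn {__version__}",
        },
    }
    physio_io.write_json(outdir / "pooled_summary.json", payload)
    pooled_cdf.to_csv(outdir / "pooled_cdf.tsv", sep="\t", index=False,
                      float_format="%.6f")
    return payload


# ---------------------------------------------------------------------------
# envelope TSV helpers


def _write_envelope(path: Path, env: ipu_segment.Envelope) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("time_s\trms\n")
        for t, v in zip(env.times, env.values):
            fh.write(f"{t:.6f}\t{float(v)!r}\n")


def _read_envelope(path: Path) -> ipu_segment.Envelope:
    df = pd.read_csv(path, sep="\t")
    return ipu_segment.Envelope(
        times=df["time_s"].to_numpy(), values=df["rms"].to_numpy()
    )
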