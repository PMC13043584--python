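"""End-to-end orchestration: simulate -> matrices -> smoothing -> sleep ->
features -> task adjustment -> modeling, with a reproducibility manifest.

Every stage is seeded from the single pipeline seed, filter decisions are
recorded with reason codes, and rerunning with the same configuration
reproduces all outputs byte-for-byte (manifest hashes are compared in
tests).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feats
from . import matrices, modeling, sleep, smoothing, tasks
from .core_io import TypingSession, sessionize
from .synthetic import CohortConfig, CohortStreams, GroundTruth, generate_cohort

PRIOR_WEEK = pd.Timedelta(days=7)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    smoothing: smoothing.SmoothingConfig = field(default_factory=smoothing.SmoothingConfig)
    modeling: modeling.ModelingConfig = field(default_factory=modeling.ModelingConfig)
    include_regularity: bool = True
    run_features: bool = True
    run_model: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed


@dataclass
class ParticipantDiurnal:
    participant_id: str
    counts: matrices.ActivityMatrix
    speed: matrices.ActivityMatrix
    svd: smoothing.GraphSVDResult
    sleep: sleep.SleepLabelMatrix
    # filled lazily by the feature stage
    sessions: list[TypingSession] | None = None
    orientation: feats.OrientationModel | None = None


@dataclass
class RunResult:
    config: PipelineConfig
    streams: CohortStreams
    truth: GroundTruth
    participants: dict[str, ParticipantDiurnal]
    drops: dict[str, str]
    adjusted_tasks: pd.DataFrame
    feature_table: pd.DataFrame
    modeling: dict | None
    manifest: dict


def process_participant(
    keystrokes: pd.DataFrame,
    config: smoothing.SmoothingConfig,
) -> ParticipantDiurnal:
    """Run one participant's diurnal stages: matrices, filters, smoothing,
    sleep labels.

    Raises :class:`matrices.InsufficientDataError` when the participant or
    their surviving days fail the activity filters.
    """
    pid = str(keystrokes["participant_id"].iloc[0])
    counts, speed = matrices.build_matrices(keystrokes)
    decision = matrices.apply_participant_filters(counts)
    if not decision.keep:
        raise matrices.InsufficientDataError(
            "participant filter: " + ", ".join(decision.reasons))
    counts, speed = matrices.apply_week_filters(counts, speed)
    result, _ = smoothing.smooth_participant(counts, speed, config)
    labels = sleep.estimate_sleep(result, counts.dates, pid)
    return ParticipantDiurnal(pid, counts, speed, result, labels)


def _window_sessions(sessions, lo, hi):
    return [s for s in sessions if lo <= s.start <= hi]


def prepare_sessions(
    participants: dict[str, ParticipantDiurnal],
    streams: CohortStreams, seed: int = 0,
) -> None:
    """Sessionize streams and fit orientation models for the feature stage."""
    for pid, part in participants.items():
        if part.sessions is None:
            ks = streams.keystrokes[streams.keystrokes["participant_id"] == pid]
            ac = streams.accel[streams.accel["participant_id"] == pid]
            part.sessions = sessionize(ks.reset_index(drop=True),
                                       ac.reset_index(drop=True))
        if part.orientation is None:
            part.orientation = feats.fit_orientation_model(part.sessions, seed=seed)


def build_feature_table(
    participants: dict[str, ParticipantDiurnal],
    task_frame: pd.DataFrame,
    include_regularity: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-task feature table joined to adjusted dTMT-B times.

    Tasks are numbered and filtered, matched to their +-3 h typing window
    (>= 20 keystrokes), and z-scored within task-number groups. Regularity
    features use W* rows and sleep quantities from the 7 days before the
    task and require at least 5 such rows. ``prepare_sessions`` must have
    populated sessions and orientation models.

    Returns (feature table of retained tasks, adjusted-task ledger).
    """
    numbered = tasks.number_and_filter_tasks(task_frame)
    ks_cache = {pid: pd.concat([s.keystrokes for s in part.sessions],
                               ignore_index=True)
                for pid, part in participants.items()}
    rows = []
    for idx, task in numbered.iterrows():
        if not task["included"]:
            continue
        pid = task["participant_id"]
        part = participants.get(pid)
        if part is None:
            numbered.loc[idx, "included"] = False
            numbered.loc[idx, "exclusion_reason"] = "participant dropped by activity filters"
            continue
        t = pd.Timestamp(task["timestamp"])
        window = tasks.match_typing_window(t, ks_cache[pid])
        if not window["accepted"]:
            numbered.loc[idx, "included"] = False
            numbered.loc[idx, "exclusion_reason"] = window["reason"]
            continue
        wsessions = _window_sessions(part.sessions, t - tasks.WINDOW_HALF_WIDTH,
                                     t + tasks.WINDOW_HALF_WIDTH)
        prior = _window_sessions(part.sessions, t - PRIOR_WEEK, t)
        row = {"participant_id": pid, "task_number": int(task["task_number"]),
               "timestamp": t, "task_index": idx}
        row.update(feats.compute_typing_features(wsessions))
        row.update(feats.compute_accel_features(wsessions, part.orientation, prior))
        if row["typingSpeed"] is None:
            numbered.loc[idx, "included"] = False
            numbered.loc[idx, "exclusion_reason"] = "no two-handed session in window"
            continue
        if include_regularity:
            day0 = t.normalize()
            in_week = ((part.counts.dates >= day0 - PRIOR_WEEK)
                       & (part.counts.dates < day0))
            if in_week.sum() >= feats.MIN_REGULARITY_ROWS:
                wrows = part.svd.clamped_trajectory(0)[in_week]
                pmask = ((part.sleep.period_dates >= day0 - PRIOR_WEEK)
                         & (part.sleep.period_dates < day0))
                row.update(feats.compute_regularity_features(
                    wrows, part.sleep.daily_sleep_hours[pmask]))
            else:
                numbered.loc[idx, "included"] = False
                numbered.loc[idx, "exclusion_reason"] = "fewer than 5 diurnal rows in prior week"
                continue
        rows.append(row)

    adjusted = tasks.adjust_times(numbered)
    table = pd.DataFrame(rows)
    if table.empty:
        return table, adjusted
    table = table.merge(
        adjusted.loc[adjusted["included"],
                     ["participant_id", "task_number", "adjusted_time"]],
        on=["participant_id", "task_number"], how="inner")
    table = feats.center_features(table)
    return table, adjusted


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline on a synthetic cohort and build the manifest."""
    config = config or PipelineConfig()
    streams, truth = generate_cohort(config.cohort)

    participants: dict[str, ParticipantDiurnal] = {}
    drops: dict[str, str] = {}
    for pid, ks in streams.keystrokes.groupby("participant_id", sort=True):
        try:
            participants[str(pid)] = process_participant(
                ks.reset_index(drop=True), config.smoothing)
        except matrices.InsufficientDataError as exc:
            drops[str(pid)] = str(exc)

    if config.run_features:
        prepare_sessions(participants, streams, seed=config.seed)
        table, adjusted = build_feature_table(participants, streams.tasks,
                                              config.include_regularity)
    else:
        table = pd.DataFrame()
        adjusted = tasks.adjust_times(
            tasks.number_and_filter_tasks(streams.tasks))

    model_out = None
    if config.run_model and not table.empty:
        cand = feats.candidate_columns(table)
        complete = table.dropna(subset=cand + [modeling.TARGET])
        if complete["participant_id"].nunique() >= 5:
            model_out = modeling.run_modeling(complete, cand,
                                              config.modeling, seed=config.seed)

    n_tasks = len(adjusted)
    n_kept = int(adjusted["included"].sum()) if n_tasks else 0
    manifest = {
        "seed": config.seed,
        "stages": {
            "simulate": {"keystrokes": len(streams.keystrokes),
                         "accel": len(streams.accel),
                         "tasks": len(streams.tasks),
                         "phq": len(streams.phq)},
            "participants": {
                "rows_in": int(streams.keystrokes["participant_id"].nunique()),
                "rows_out": len(participants),
                "rows_filtered": len(drops),
                "drop_reasons": drops},
            "tasks": {"rows_in": n_tasks, "rows_out": n_kept,
                      "rows_filtered": n_tasks - n_kept},
            "features": {"rows_out": len(table)},
        },
        "hashes": {
            "keystrokes": _hash_frame(streams.keystrokes),
            "tasks": _hash_frame(streams.tasks),
            "adjusted_tasks": _hash_frame(adjusted.drop(columns=["timestamp"])),
            "feature_table": _hash_frame(table.round(12)) if len(table) else "",
        },
    }
    if model_out is not None:
        manifest["modeling"] = {
            "selected": model_out["selected"],
            "test_participants": model_out["split"].test_participants,
            "rmse": {k: r.rmse for k, r in model_out["reports"].items()},
        }

    result = RunResult(config, streams, truth, participants, drops,
                       adjusted, table, model_out, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        streams.write(outdir)
        truth.to_json(outdir / "ground_truth.json")
        if len(table):
            table.to_csv(outdir / "feature_table.csv", index=False)
        adjusted.to_csv(outdir / "adjusted_tasks.csv", index=False)
        for pid, part in participants.items():
            part.sleep.to_frame().to_csv(outdir / f"sleep_{pid}.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result


def sleep_recovery(result: RunResult) -> pd.DataFrame:
    """Hour-level agreement between estimated and planted sleep labels,
    one row per surviving participant."""
    rows = []
    for pid, part in result.participants.items():
        truth_labels = result.truth.label_matrix_for_dates(pid, part.sleep.dates)
        rows.append({
            "participant_id": pid,
            "agreement": sleep.hour_agreement(part.sleep.labels, truth_labels),
            "median_sleep_h": float(np.median(part.sleep.daily_sleep_hours))
            if len(part.sleep.daily_sleep_hours) else np.nan,
        })
    return pd.DataFrame(rows)
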