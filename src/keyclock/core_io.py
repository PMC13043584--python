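"""Data model, readers/writers, and sessionization for passive typing streams.

Four record kinds flow through the pipeline:

* keystroke events — timestamp, key category and press duration, but no text;
* accelerometer samples — tri-axial readings attached to typing sessions;
* task records — digital Trail-Making-Test-B administrations (completion
  time, error count, layout variant);
* PHQ self-reports — the 8-item depression questionnaire (suicidality item
  omitted at the source).

Timestamps are the participant's local wall-clock time throughout: every
downstream structure is indexed by local hour-of-day, so no timezone
arithmetic is ever performed.

Streams are stored as JSONL (one record per line) or CSV with headers; the
in-memory container is a :class:`pandas.DataFrame` with the schemas declared
in :data:`SCHEMAS`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("keyclock")

KEY_CATEGORIES = (
    "alphanumeric",
    "backspace",
    "autocorrect",
    "punctuation",
    "special",
    "other",
)
HAND_MODES = ("one", "two", "unknown")

#: Default gap (seconds) between consecutive keystrokes that starts a new
#: typing session when no session ids are present in the stream.
DEFAULT_SESSION_GAP = 5.0

#: Accelerometer samples matching no session are attached to the nearest
#: session if within this many seconds, else dropped.
ACCEL_ATTACH_TOLERANCE = 60.0


class SchemaError(ValueError):
    """A stream violated its declared schema; message cites field and line."""


# required columns, optional columns, per-kind row validators
SCHEMAS: dict[str, dict] = {
    "keystrokes": {
        "required": ["participant_id", "timestamp", "key_category", "press_duration"],
        "optional": ["session_id", "hand_mode"],
    },
    "accel": {
        "required": ["participant_id", "session_id", "timestamp", "x", "y", "z"],
        "optional": [],
    },
    "tasks": {
        "required": [
            "participant_id",
            "timestamp",
            "completion_time",
            "n_errors",
            "layout_variant",
        ],
        "optional": [],
    },
    "phq": {
        "required": ["participant_id", "timestamp"]
        + [f"item_{k}" for k in range(1, 9)]
        + ["total"],
        "optional": [],
    },
}


@dataclass
class KeystrokeEvent:
    participant_id: str
    timestamp: pd.Timestamp
    key_category: str
    press_duration: float
    session_id: str | None = None
    hand_mode: str = "unknown"

    def __post_init__(self) -> None:
        if self.key_category not in KEY_CATEGORIES:
            raise SchemaError(f"key_category {self.key_category!r} not in {KEY_CATEGORIES}")
        if not np.isfinite(self.press_duration) or self.press_duration < 0:
            raise SchemaError("press_duration must be finite and >= 0")


@dataclass
class AccelSample:
    participant_id: str
    session_id: str
    timestamp: pd.Timestamp
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for axis in (self.x, self.y, self.z):
            if not np.isfinite(axis) or abs(axis) > 4.0:
                raise SchemaError("accelerometer axis must be finite and |axis| <= 4 g")


@dataclass
class TaskRecord:
    participant_id: str
    timestamp: pd.Timestamp
    completion_time: float
    n_errors: int
    layout_variant: int

    def __post_init__(self) -> None:
        if not self.completion_time > 0:
            raise SchemaError("completion_time must be > 0")
        if self.n_errors < 0:
            raise SchemaError("n_errors must be >= 0")
        if not 1 <= self.layout_variant <= 12:
            raise SchemaError("layout_variant must be in 1..12")


@dataclass
class PHQRecord:
    participant_id: str
    timestamp: pd.Timestamp
    items: list[int]
    total: int

    def __post_init__(self) -> None:
        if len(self.items) != 8:
            raise SchemaError("PHQ requires exactly 8 items")
        for v in self.items:
            if v not in (0, 1, 2, 3):
                raise SchemaError(f"PHQ item score {v} outside 0-3")
        if self.total != sum(self.items):
            raise SchemaError("PHQ total must equal the sum of the items")


@dataclass
class TypingSession:
    """A contiguous burst of typing with its accelerometer samples."""

    session_id: str
    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    hand_mode: str
    keystrokes: pd.DataFrame
    accel: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.keystrokes)


def _validate_frame(df: pd.DataFrame, kind: str) -> list[str]:
    """Return a list of 'line N: message' strings for rows violating invariants.

    Line numbers are 1-based positions in the stream (header excluded for CSV).
    """
    problems: list[str] = []

    def flag(mask: pd.Series, message: str) -> None:
        for pos in np.flatnonzero(np.asarray(mask)):
            problems.append(f"line {pos + 1}: {message}")

    if kind == "keystrokes":
        flag(~df["key_category"].isin(KEY_CATEGORIES), "key_category outside enum")
        flag(~np.isfinite(df["press_duration"]) | (df["press_duration"] < 0),
             "press_duration must be finite and >= 0")
        if "hand_mode" in df.columns:
            flag(~df["hand_mode"].isin(HAND_MODES), "hand_mode outside enum")
    elif kind == "accel":
        for axis in ("x", "y", "z"):
            flag(~np.isfinite(df[axis]) | (df[axis].abs() > 4.0),
                 f"{axis}-axis must be finite and |{axis}| <= 4 g")
    elif kind == "tasks":
        flag(df["completion_time"] <= 0, "completion_time must be > 0")
        flag(df["n_errors"] < 0, "n_errors must be >= 0")
        flag(~df["layout_variant"].between(1, 12), "layout_variant must be in 1..12")
    elif kind == "phq":
        items = df[[f"item_{k}" for k in range(1, 9)]]
        flag((items < 0).any(axis=1) | (items > 3).any(axis=1),
             "PHQ item score outside 0-3")
        flag(df["total"] != items.sum(axis=1), "PHQ total must equal sum of items")
    return problems


def load_stream(path: str | Path, record_kind: str) -> pd.DataFrame:
    """Load a validated record stream sorted by (participant_id, timestamp).

    ``path`` must be a CSV (with header) or JSONL file whose columns match the
    declared schema for ``record_kind``. Malformed rows raise
    :class:`SchemaError` citing field and line number.
    """
    if record_kind not in SCHEMAS:
        raise ValueError(f"unknown record kind {record_kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=SCHEMAS[record_kind]["required"])

    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        df = pd.read_json(path, lines=True, convert_dates=False)
    else:
        df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=SCHEMAS[record_kind]["required"])

    missing = [c for c in SCHEMAS[record_kind]["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required field(s) {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path.name}: unparsable timestamp ({exc})") from exc

    problems = _validate_frame(df, record_kind)
    if problems:
        shown = "; ".join(problems[:10])
        raise SchemaError(f"{path.name}: {len(problems)} malformed row(s): {shown}")

    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    return df.reset_index(drop=True)


def write_stream(df: pd.DataFrame, path: str | Path) -> None:
    """Write a record stream as CSV or JSONL according to the file extension."""
    path = Path(path)
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S.%f"
        )
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        with open(path, "w") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        out.to_csv(path, index=False)


def _assign_session_ids(events: pd.DataFrame, gap_threshold: float) -> pd.Series:
    """Derive session ids from inter-keystroke gaps, per participant."""
    ts = pd.to_datetime(events["timestamp"])
    gaps = ts.diff().dt.total_seconds()
    new_participant = events["participant_id"] != events["participant_id"].shift()
    breaks = new_participant | (gaps > gap_threshold) | gaps.isna()
    counter = breaks.cumsum()
    return events["participant_id"].astype(str) + "-s" + counter.astype(str)


def sessionize(
    events: pd.DataFrame,
    accel: pd.DataFrame | None = None,
    gap_threshold: float = DEFAULT_SESSION_GAP,
) -> list[TypingSession]:
    """Group keystrokes (and their accelerometer samples) into typing sessions.

    Events carrying a ``session_id`` column with no missing values are grouped
    by it; otherwise a new session starts whenever the gap to the previous
    keystroke exceeds ``gap_threshold`` seconds. Every keystroke belongs to
    exactly one session. Accelerometer samples are matched by session id when
    present, else to the session whose [start, end] span contains them, else
    to the nearest session within 60 s (logged), else dropped with a warning.
    """
    if events.empty:
        return []
    events = events.sort_values(["participant_id", "timestamp"], kind="stable")
    events = events.reset_index(drop=True)
    events["timestamp"] = pd.to_datetime(events["timestamp"])

    if "session_id" in events.columns and events["session_id"].notna().all():
        sid = events["session_id"].astype(str)
    else:
        sid = _assign_session_ids(events, gap_threshold)
    events = events.assign(session_id=sid)

    has_accel = accel is not None and len(accel) > 0
    if has_accel:
        accel = accel.copy()
        accel["timestamp"] = pd.to_datetime(accel["timestamp"])

    # re-sort so each session is one contiguous block, then slice blocks
    events = events.sort_values(["participant_id", "session_id", "timestamp"],
                                kind="stable").reset_index(drop=True)
    codes, _ = pd.factorize(events["session_id"])
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1, [len(events)]])
    ts = events["timestamp"].to_numpy()
    sids = events["session_id"].to_numpy()
    pids = events["participant_id"].to_numpy()
    hands = (events["hand_mode"].to_numpy()
             if "hand_mode" in events.columns else None)

    sessions: list[TypingSession] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        hand = str(hands[a]) if hands is not None and not pd.isna(hands[a]) else "unknown"
        sessions.append(
            TypingSession(
                session_id=str(sids[a]),
                participant_id=str(pids[a]),
                start=pd.Timestamp(ts[a]),
                end=pd.Timestamp(ts[b - 1]),
                hand_mode=hand,
                keystrokes=events.iloc[a:b],
                accel=pd.DataFrame(),
            )
        )
    sessions.sort(key=lambda s: (s.participant_id, s.start))

    if has_accel:
        by_id = {sess.session_id: sess for sess in sessions}
        known = (accel["session_id"].astype(str).isin(by_id)
                 if "session_id" in accel.columns
                 else pd.Series(False, index=accel.index))
        for s, grp in accel[known].groupby(accel.loc[known, "session_id"].astype(str)):
            by_id[s].accel = grp
        orphans = accel[~known]
        if len(orphans):
            starts = np.array([sess.start.value for sess in sessions], dtype=np.int64)
            ends = np.array([sess.end.value for sess in sessions], dtype=np.int64)
            for _, row in orphans.iterrows():
                t = row["timestamp"].value
                inside = np.flatnonzero((starts <= t) & (t <= ends))
                if len(inside):
                    target = sessions[inside[0]]
                else:
                    dist = np.minimum(np.abs(starts - t), np.abs(ends - t)) / 1e9
                    j = int(np.argmin(dist))
                    if dist[j] <= ACCEL_ATTACH_TOLERANCE:
                        target = sessions[j]
                        logger.info(
                            "accel sample at %s attached to nearest session %s (%.1fs away)",
                            row["timestamp"], target.session_id, dist[j],
                        )
                    else:
                        warnings.warn(
                            f"accel sample at {row['timestamp']} matches no session; dropped",
                            stacklevel=2,
                        )
                        continue
                target.accel = pd.concat(
                    [target.accel, row.to_frame().T], ignore_index=True
                )
    return sessions


def sessions_to_frame(sessions: list[TypingSession]) -> pd.DataFrame:
    """One summary row per session: id, participant, span, hand mode, size."""
    return pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "participant_id": [s.participant_id for s in sessions],
            "start": [s.start for s in sessions],
            "end": [s.end for s in sessions],
            "hand_mode": [s.hand_mode for s in sessions],
            "n_keystrokes": [len(s) for s in sessions],
        }
    )
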