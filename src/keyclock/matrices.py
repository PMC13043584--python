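"""Days x 24 typing-activity matrices with participant and week filtering.

Each participant's keystrokes become two matrices sharing the same calendar
rows: keystroke counts ``k[day, hour]`` and hourly typing speed (median
interkey delay over alphanumeric->alphanumeric transitions, seconds). Hours
with no activity are zero-filled; the first and last calendar days are
trimmed as potentially incomplete.

Participants with a mean active-hour fraction below 20% or a median daily
keystroke total below 50 are excluded, the same thresholds are applied to
sliding 7-day windows (stride one day; a day survives if it lies in at least
one passing window), and participants with fewer than 7 surviving days are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import TypingSession

ACTIVE_HOUR_FRACTION_MIN = 0.20
MEDIAN_DAILY_KEYSTROKES_MIN = 50.0
MIN_SURVIVING_DAYS = 7
WEEK_WINDOW = 7


class InsufficientDataError(ValueError):
    """Too little typing data survives trimming or filtering."""


class DegenerateInputError(ValueError):
    pass


@dataclass
class ActivityMatrix:
    participant_id: str
    dates: pd.DatetimeIndex          # one row per calendar day, chronological
    values: np.ndarray               # (n_days, 24)
    kind: str                        # "count" or "speed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 24:
            raise ValueError("activity matrix must be days x 24")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("dates and rows must align")
        if pd.Index(self.dates).has_duplicates:
            raise ValueError("duplicate dates")
        if not pd.Index(self.dates).is_monotonic_increasing:
            raise ValueError("dates must be chronological")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def daily_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def active_hour_fraction(self) -> np.ndarray:
        return (self.values > 0).sum(axis=1) / 24.0

    def take_days(self, keep: np.ndarray) -> "ActivityMatrix":
        return ActivityMatrix(self.participant_id, self.dates[keep],
                              self.values[keep], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates.strftime("%Y-%m-%d"),
                            columns=[f"h{h:02d}" for h in range(24)])


@dataclass
class FilterDecision:
    participant_id: str
    keep: bool
    reasons: list[str]
    active_hour_fraction: float
    median_daily_keystrokes: float


def _keystroke_frame(sessions) -> pd.DataFrame:
    if isinstance(sessions, pd.DataFrame):
        return sessions
    frames = [s.keystrokes for s in sessions if len(s.keystrokes)]
    if not frames:
        return pd.DataFrame(columns=["participant_id", "timestamp", "key_category",
                                     "session_id"])
    return pd.concat(frames, ignore_index=True)


def _aa_ikds(ks: pd.DataFrame) -> pd.DataFrame:
    """Interkey delays for alphanumeric->alphanumeric transitions.

    Pairs are consecutive keystrokes of the same session falling in the same
    calendar hour (a transition crossing the hour boundary belongs to no
    hour); each delay is assigned to the timestamp of the first keystroke.
    """
    ks = ks.sort_values("timestamp", kind="stable")
    group = ks["session_id"] if "session_id" in ks.columns else pd.Series(0, index=ks.index)
    same_session = group == group.shift(-1)
    hour = ks["timestamp"].dt.floor("h")
    same_hour = hour == hour.shift(-1)
    ikd = (ks["timestamp"].shift(-1) - ks["timestamp"]).dt.total_seconds()
    aa = (ks["key_category"].eq("alphanumeric")
          & ks["key_category"].shift(-1).eq("alphanumeric"))
    mask = same_session & same_hour & aa & ikd.notna()
    return pd.DataFrame({"timestamp": ks.loc[mask, "timestamp"],
                         "ikd": ikd[mask]})


def build_matrices(sessions) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Build (counts, speed) matrices for one participant, first/last day trimmed.

    ``sessions`` is a list of :class:`TypingSession` or a keystroke
    DataFrame. The speed cell is the median alphanumeric->alphanumeric
    interkey delay of the hour, 0 where no such transition exists.
    """
    ks = _keystroke_frame(sessions)
    if ks.empty:
        raise InsufficientDataError("no keystrokes")
    pid = str(ks["participant_id"].iloc[0])
    ks = ks.copy()
    ks["timestamp"] = pd.to_datetime(ks["timestamp"])

    days = ks["timestamp"].dt.normalize()
    first, last = days.min(), days.max()
    dates = pd.date_range(first, last, freq="D")
    if len(dates) < 3:
        raise InsufficientDataError("fewer than 3 calendar days of data")
    dates = dates[1:-1]  # trim potentially incomplete first/last days
    day_index = pd.Index(dates)

    counts = np.zeros((len(dates), 24))
    grouped = ks.groupby([days, ks["timestamp"].dt.hour]).size()
    for (d, h), c in grouped.items():
        r = day_index.get_indexer([d])[0]
        if r >= 0:
            counts[r, h] = c

    speed = np.zeros((len(dates), 24))
    ikds = _aa_ikds(ks)
    if len(ikds):
        med = ikds.groupby([ikds["timestamp"].dt.normalize(),
                            ikds["timestamp"].dt.hour])["ikd"].median()
        for (d, h), v in med.items():
            r = day_index.get_indexer([d])[0]
            if r >= 0:
                speed[r, h] = v

    return (ActivityMatrix(pid, dates, counts, "count"),
            ActivityMatrix(pid, dates, speed, "speed"))


def apply_participant_filters(counts: ActivityMatrix) -> FilterDecision:
    """Keep iff mean active-hour fraction >= 20% and median daily keystrokes >= 50."""
    frac = float(counts.active_hour_fraction().mean())
    med = float(np.median(counts.daily_totals()))
    reasons = []
    if frac < ACTIVE_HOUR_FRACTION_MIN:
        reasons.append("active-hour fraction")
    if med < MEDIAN_DAILY_KEYSTROKES_MIN:
        reasons.append("median daily keystrokes")
    return FilterDecision(counts.participant_id, not reasons, reasons, frac, med)


def _window_passes(counts: np.ndarray) -> bool:
    frac = (counts > 0).sum(axis=1).mean() / 24.0
    med = np.median(counts.sum(axis=1))
    return frac >= ACTIVE_HOUR_FRACTION_MIN and med >= MEDIAN_DAILY_KEYSTROKES_MIN


def apply_week_filters(
    counts: ActivityMatrix, speed: ActivityMatrix
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Remove days contained in no passing 7-day window (stride one day).

    A window passes iff its 7 consecutive rows meet both activity thresholds.
    Raises :class:`InsufficientDataError` when fewer than 7 days survive
    (the participant is dropped).
    """
    n = counts.n_days
    keep = np.zeros(n, dtype=bool)
    for s in range(0, n - WEEK_WINDOW + 1):
        if _window_passes(counts.values[s:s + WEEK_WINDOW]):
            keep[s:s + WEEK_WINDOW] = True
    if keep.sum() < MIN_SURVIVING_DAYS:
        raise InsufficientDataError(
            f"only {int(keep.sum())} day(s) survive 7-day window filtering")
    return counts.take_days(keep), speed.take_days(keep)


def normalize_counts(counts: ActivityMatrix) -> ActivityMatrix:
    """Divide every cell by the participant's grand keystroke total."""
    total = counts.values.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero count matrix cannot be normalized")
    return ActivityMatrix(counts.participant_id, counts.dates,
                          counts.values / total, "count")
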