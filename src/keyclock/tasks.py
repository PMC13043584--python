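"""Numbering, filtering, and practice adjustment of dTMT-B records.

Repeated trail-making administrations improve with practice. Tasks are
numbered chronologically per participant *before* any filtering, truncated
to the first six, stripped of 95th-percentile outliers in errors or
completion time, matched to a typing window around the task timestamp, and
finally z-scored within task-number groups (population SD) so the adjusted
time is practice-free: each group has mean 0 and SD 1 exactly, hence so does
the pooled distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_TASKS_PER_PARTICIPANT = 6
PERCENTILE_CUT = 95.0
#: half-width of the "six hour range around" a task timestamp
WINDOW_HALF_WIDTH = pd.Timedelta(hours=3)
MIN_WINDOW_KEYSTROKES = 20


@dataclass
class PercentileCutoffs:
    errors: float
    completion_time: float


def number_and_filter_tasks(
    tasks: pd.DataFrame,
    percentile_mode: str = "data",
    fixed_cutoffs: PercentileCutoffs | None = None,
    at_or_above: bool = True,
) -> pd.DataFrame:
    """Assign task numbers, keep the first six, drop percentile outliers.

    Numbers are assigned on the full chronological list per participant.
    With ``percentile_mode="data"`` the 95th percentiles of errors and
    completion time are computed across the retained (first-six) pool;
    ``"fixed"`` uses the supplied cutoffs instead. Tasks at or above either
    cutoff are excluded (``at_or_above=False`` switches to strictly-above).

    Returns one row per input task with ``task_number``, ``included`` and
    ``exclusion_reason`` columns.
    """
    if tasks.empty:
        return tasks.assign(task_number=pd.Series(dtype=int),
                            included=pd.Series(dtype=bool),
                            exclusion_reason=pd.Series(dtype=object))
    df = tasks.sort_values(["participant_id", "timestamp"], kind="stable").copy()
    df["task_number"] = df.groupby("participant_id").cumcount() + 1
    df["included"] = True
    df["exclusion_reason"] = ""

    late = df["task_number"] > MAX_TASKS_PER_PARTICIPANT
    df.loc[late, "included"] = False
    df.loc[late, "exclusion_reason"] = "beyond first six tasks"

    pool = df[df["included"]]
    if percentile_mode == "data":
        cut = PercentileCutoffs(
            errors=float(np.percentile(pool["n_errors"], PERCENTILE_CUT)),
            completion_time=float(np.percentile(pool["completion_time"], PERCENTILE_CUT)),
        )
    elif percentile_mode == "fixed":
        if fixed_cutoffs is None:
            raise ValueError("fixed percentile mode requires cutoffs")
        cut = fixed_cutoffs
    else:
        raise ValueError(f"unknown percentile_mode {percentile_mode!r}")

    if at_or_above:
        bad = (df["n_errors"] >= cut.errors) | (df["completion_time"] >= cut.completion_time)
    else:
        bad = (df["n_errors"] > cut.errors) | (df["completion_time"] > cut.completion_time)
    bad &= df["included"]
    df.loc[bad, "included"] = False
    df.loc[bad, "exclusion_reason"] = "95th-percentile outlier"
    return df.reset_index(drop=True)


def match_typing_window(
    task_timestamp: pd.Timestamp, keystrokes: pd.DataFrame,
    accel: pd.DataFrame | None = None,
    half_width: pd.Timedelta = WINDOW_HALF_WIDTH,
    min_keystrokes: int = MIN_WINDOW_KEYSTROKES,
) -> dict:
    """Keystrokes/accel within the closed +-3 h window around a task.

    Returns ``{"accepted": bool, "keystrokes": ..., "accel": ...,
    "reason": str}``; a task is rejected when fewer than 20 keystrokes fall
    inside the window (boundary instants included).
    """
    t = pd.Timestamp(task_timestamp)
    lo, hi = t - half_width, t + half_width
    ts = pd.to_datetime(keystrokes["timestamp"])
    ks = keystrokes[(ts >= lo) & (ts <= hi)]
    out = {"keystrokes": ks, "accel": pd.DataFrame(), "accepted": True, "reason": ""}
    if accel is not None and len(accel):
        ats = pd.to_datetime(accel["timestamp"])
        out["accel"] = accel[(ats >= lo) & (ats <= hi)]
    if len(ks) < min_keystrokes:
        out["accepted"] = False
        out["reason"] = f"only {len(ks)} keystrokes in +-{half_width} window"
    return out


def adjust_times(tasks: pd.DataFrame) -> pd.DataFrame:
    """Z-score completion times within task-number groups (population SD).

    Included rows gain an ``adjusted_time`` column; singleton or zero-SD
    groups map to 0 and are flagged in ``adjustment_flag``.
    """
    df = tasks.copy()
    df["adjusted_time"] = np.nan
    df["adjustment_flag"] = ""
    inc = df["included"] if "included" in df.columns else pd.Series(True, index=df.index)
    for number, grp in df[inc].groupby("task_number"):
        t = grp["completion_time"].to_numpy(dtype=float)
        sd = t.std(ddof=0)
        if len(t) < 2 or sd == 0:
            df.loc[grp.index, "adjusted_time"] = 0.0
            df.loc[grp.index, "adjustment_flag"] = "degenerate group"
        else:
            df.loc[grp.index, "adjusted_time"] = (t - t.mean()) / sd
    return df
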