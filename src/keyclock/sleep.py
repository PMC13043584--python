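"""Sleep/wake labeling from the smoothed typing trajectory W*.

Estimated sleep is the prolonged contiguous block of smoothed zero typing
activity per relative 24 h period — a behavioral proxy, not measured sleep.
The stages are:

1. binarize the (clamped, nonnegative) days x 24 trajectory: > epsilon -> 1;
2. flood-fill the zero cells (4-connected, treating the matrix as a 2-D
   image) from a seed in the least-active hour column to find the main
   consistent inactivity block;
3. extend each day's block backwards across midnight through zero cells of
   the previous day (the image view cannot cross the left edge);
4. slide an 8 h window in 2 h steps over the flattened label sequence,
   flipping interior runs of <= 2 h flanked by the opposite label;
5. enforce one contiguous sleep block per relative 24 h period (anchored
   mid-wake, at the hour least often labeled sleep), keeping the longest
   run per period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import flood

from .smoothing import GraphSVDResult

SMOOTH_WINDOW_H = 8   # sliding-window length for label cleanup
SMOOTH_STRIDE_H = 2   # window stride
SMOOTH_MAX_GAP_H = 2  # maximal run length that gets flipped

SLEEP, WAKE = 1, 0


@dataclass
class SleepLabelMatrix:
    participant_id: str
    dates: pd.DatetimeIndex
    labels: np.ndarray                 # (n_days, 24), 1 = sleep
    daily_sleep_hours: np.ndarray      # one entry per full relative 24 h period
    period_dates: pd.DatetimeIndex = field(default=None)  # day each period starts in
    anchor_hour: int = 0               # modal sleep-onset hour anchoring periods

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.dates.strftime("%Y-%m-%d"),
                            columns=[f"h{h:02d}" for h in range(24)])


def binarize(wstar: np.ndarray, eps: float) -> np.ndarray:
    """1 where smoothed activity exceeds eps, else 0 (candidate sleep)."""
    w = np.clip(np.asarray(wstar, dtype=float), 0.0, None)
    return (w > eps).astype(np.uint8)


def flood_fill_inactive(binary: np.ndarray) -> np.ndarray:
    """4-connected component of zero cells seeded at the least-active hour.

    The seed is the zero cell in the hour column with minimal column mean
    (lowest hour index on ties), on the earliest day holding a zero there.
    """
    binary = np.asarray(binary)
    if not (binary == 0).any():
        warnings.warn("no zero cells: no candidate sleep block", stacklevel=2)
        return np.zeros_like(binary, dtype=bool)
    col_mean = binary.mean(axis=0)
    # hours ordered by activity; the minimal-mean column necessarily has zeros
    hour = int(np.argmin(col_mean))
    day = int(np.flatnonzero(binary[:, hour] == 0)[0])
    return flood(binary, (day, hour), connectivity=1)


def extend_pre_midnight(mask: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Walk backwards from midnight through zero cells of the previous day.

    For every day whose hour-0 cell is masked, hours 23, 22, ... of the
    previous row join the mask while their binarized value is 0.
    """
    out = mask.copy()
    for d in range(1, mask.shape[0]):
        if out[d, 0]:
            h = 23
            while h >= 0 and binary[d - 1, h] == 0:
                out[d - 1, h] = True
                h -= 1
    return out


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (start, stop, value), stop exclusive."""
    runs = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            runs.append((start, k, int(labels[start])))
            start = k
    return runs


def smooth_labels(labels: np.ndarray) -> np.ndarray:
    """Remove small gaps with an 8 h sliding window advancing 2 h at a time.

    Within each window, the leftmost maximal run of length <= 2 flanked on
    both sides (within the window) by the opposite label is flipped;
    flipping repeats until the window is stable, then the window advances on
    the running result. A second full pass is a no-op.
    """
    seq = np.asarray(labels).astype(np.uint8).copy()
    n = len(seq)
    if n == 0:
        return seq
    starts = range(0, max(n - SMOOTH_WINDOW_H, 0) + 1, SMOOTH_STRIDE_H)
    for s in starts:
        window = seq[s:s + SMOOTH_WINDOW_H]
        changed = True
        while changed:
            changed = False
            for a, b, v in _runs(window):
                if a == 0 or b == len(window):
                    continue  # not flanked within the window
                if b - a <= SMOOTH_MAX_GAP_H:
                    window[a:b] = 1 - v
                    changed = True
                    break
    return seq


def _period_slices(n: int, anchor: int) -> list[tuple[int, int]]:
    """Relative 24 h periods [anchor + 24k, anchor + 24(k+1)) plus partials."""
    slices = []
    if anchor > 0:
        slices.append((0, min(anchor, n)))
    s = anchor
    while s < n:
        slices.append((s, min(s + 24, n)))
        s += 24
    return slices


def enforce_single_blocks(
    labels: np.ndarray, dates: pd.DatetimeIndex, participant_id: str = ""
) -> SleepLabelMatrix:
    """Keep one contiguous sleep block per relative 24 h period.

    Periods are anchored at the hour least often labeled sleep (mid-wake),
    so a block spanning midnight is counted once even when its onset
    jitters. Within each period, the longest sleep run (earliest on ties)
    is kept and the rest relabeled wake.
    """
    seq = np.asarray(labels).astype(np.uint8).reshape(-1).copy()
    n = len(seq)
    sleep_runs = [(a, b) for a, b, v in _runs(seq) if v == SLEEP]
    if sleep_runs:
        # Cut the 24 h periods in the middle of typical wake (the hour least
        # often labeled sleep) so a sleep block spanning midnight — onset
        # jitter included — falls inside a single period instead of being
        # split at its own typical onset.
        sleep_freq = seq[: (n // 24) * 24].reshape(-1, 24).mean(axis=0)
        anchor = int(np.argmin(sleep_freq))
    else:
        warnings.warn("no sleep run detected for any period", stacklevel=2)
        anchor = 0

    periods = _period_slices(n, anchor)
    for s, e in periods:
        runs = [(a, b) for a, b, v in _runs(seq[s:e]) if v == SLEEP]
        if len(runs) > 1:
            keep = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
            for a, b in runs:
                if (a, b) != keep:
                    seq[s + a:s + b] = WAKE

    full = [(s, e) for s, e in periods if e - s == 24]
    daily = np.array([int(seq[s:e].sum()) for s, e in full], dtype=int)
    period_dates = pd.DatetimeIndex([dates[s // 24] for s, _ in full])
    for s, e in full:
        if seq[s:e].sum() == 0:
            warnings.warn(
                f"no sleep detected in the 24 h period starting {dates[s // 24].date()}",
                stacklevel=2)
    return SleepLabelMatrix(
        participant_id=participant_id,
        dates=dates,
        labels=seq.reshape(-1, 24),
        daily_sleep_hours=daily,
        period_dates=period_dates,
        anchor_hour=anchor,
    )


def estimate_sleep(
    result: GraphSVDResult, dates: pd.DatetimeIndex, participant_id: str = ""
) -> SleepLabelMatrix:
    """Full labeling stage from a smoothing result."""
    wstar = result.clamped_trajectory(0)
    binary = binarize(wstar, result.zero_tolerance)
    if (binary == 1).all():
        warnings.warn("trajectory everywhere active: no candidate sleep",
                      stacklevel=2)
    mask = flood_fill_inactive(binary)
    mask = extend_pre_midnight(mask, binary)
    seq = smooth_labels(mask.astype(np.uint8).reshape(-1))
    return enforce_single_blocks(seq, pd.DatetimeIndex(dates), participant_id)


def hour_agreement(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of grid cells where estimated and true labels agree."""
    est = np.asarray(estimated).reshape(-1)
    tru = np.asarray(truth).reshape(-1)
    if est.shape != tru.shape:
        raise ValueError("label grids must have identical shape")
    return float((est == tru).mean())


def single_block_violations(matrix: SleepLabelMatrix) -> int:
    """Count relative 24 h periods holding more than one sleep run."""
    seq = matrix.labels.reshape(-1)
    bad = 0
    for s, e in _period_slices(len(seq), matrix.anchor_hour):
        runs = [r for r in _runs(seq[s:e]) if r[2] == SLEEP]
        if len(runs) > 1:
            bad += 1
    return bad
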