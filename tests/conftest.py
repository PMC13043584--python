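import warnings

import numpy as np
import pandas as pd
import pytest

from keyclock import matrices, smoothing
from keyclock.core_io import TypingSession
from keyclock.modeling import ModelingConfig
from keyclock.pipeline import PipelineConfig, run_pipeline
from keyclock.synthetic import CohortConfig, generate_cohort

# reduced RF-only grid for fast, deterministic model fits in tests
RF_GRID = {"rf": {"criterion": ["squared_error"], "max_depth": [3, 4],
                  "min_samples_leaf": [4], "min_samples_split": [3],
                  "n_estimators": [15, 30]}}


def make_session(
    participant_id="P0", session_id="s0", start="2024-01-02 10:00:00",
    ikds=(0.2, 0.2, 0.2), categories=None, hand_mode="two",
    accel_xyz=None, press_duration=0.08,
) -> TypingSession:
    """Build a typing session from interkey delays and optional accel points."""
    start = pd.Timestamp(start)
    times = [start]
    for d in ikds:
        times.append(times[-1] + pd.Timedelta(seconds=float(d)))
    n = len(times)
    cats = list(categories) if categories is not None else ["alphanumeric"] * n
    ks = pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": times,
        "key_category": cats,
        "press_duration": press_duration,
        "session_id": session_id,
        "hand_mode": hand_mode,
    })
    accel = pd.DataFrame()
    if accel_xyz is not None:
        pts = np.atleast_2d(np.asarray(accel_xyz, dtype=float))
        accel = pd.DataFrame({
            "participant_id": participant_id, "session_id": session_id,
            "timestamp": [start] * len(pts),
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        })
    return TypingSession(session_id, participant_id, times[0], times[-1],
                         hand_mode, ks, accel)


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants x 14 days of synthetic streams plus ground truth."""
    return generate_cohort(CohortConfig(n_participants=4, n_days=14, seed=7))


@pytest.fixture(scope="session")
def participant_smoothing(small_cohort):
    """Filtered matrices and smoothing result for one synthetic participant."""
    streams, _ = small_cohort
    ks = streams.keystrokes[streams.keystrokes["participant_id"] == "P000"]
    counts, speed = matrices.build_matrices(ks)
    counts, speed = matrices.apply_week_filters(counts, speed)
    result, graph = smoothing.smooth_participant(counts, speed)
    return counts, speed, result, graph


@pytest.fixture(scope="session")
def pipeline_run():
    """A full small pipeline run with RF-only modeling."""
    cfg = PipelineConfig(
        cohort=CohortConfig(n_participants=12, n_days=18,
                            task_interval_days=3, max_tasks=5),
        modeling=ModelingConfig(grids=RF_GRID, models=("rf",)),
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)
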