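"""Typing, orientation, and regularity feature engineering.

Thirteen typing/accelerometer features are computed from the sessions in a
six-hour window around each task, five regularity/sleep features from the
smoothed trajectory W* and sleep labels of the week before the task, and
every feature is expanded into a grand-mean (``_gm``, the participant's
average — a between-person predictor) and a subject-centered (``_sc``,
observation minus that average — a within-person fluctuation) column,
giving 36 candidate predictors.

The personalized phone-orientation model is a centroid-partition (k-means)
clustering of per-session median accelerometer vectors, with the cluster
count chosen from 2..6 by the silhouette criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_io import TypingSession

TYPING_ACCEL_FEATURES = [
    "nClusters",
    "normalized_n_cluster_transitions",
    "avg_n_cluster_transitions_perSession",
    "medianX",
    "fraction_nighttime_nonUpright_sessions",
    "fraction_upright",
    "nSessions",
    "avgNkeypresses",
    "backspaceRate",
    "autocorrectRate",
    "typingSpeed",
    "varAAIKD",
    "medianPressDuration",
]
REGULARITY_FEATURES = [
    "varCircVar",
    "medAmt_noActivity",
    "varAmt_noActivity",
    "medianCosineSimilarity_1diff",
    "medianCosineSimilarity_4diff",
]
ALL_FEATURES = TYPING_ACCEL_FEATURES + REGULARITY_FEATURES

#: upright posture: phone held vertically in front of the user
UPRIGHT_X = (-0.2, 0.2)
UPRIGHT_Z_MAX = 0.1
#: non-upright: strongly tilted on x with z pointing up
NONUPRIGHT_X_ABS = 0.5
NONUPRIGHT_Z_MIN = 0.1

#: nighttime hours for the non-upright-session feature, [start, stop)
NIGHT_WINDOW = (0, 6)

CLUSTER_CANDIDATES = range(2, 7)
MIN_REGULARITY_ROWS = 5


@dataclass
class OrientationModel:
    participant_id: str
    centroids: np.ndarray               # (k, 3) in g-units
    assignments: dict[str, int]         # session_id -> centroid index
    n_clusters: int

    def assign(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.centroids[None], axis=2)
        return d.argmin(axis=1)


_REP_CACHE = "_orientation_rep"


def _xyz(accel: pd.DataFrame) -> np.ndarray:
    return np.column_stack([accel[c].to_numpy(dtype=float) for c in "xyz"])


def session_representative(session: TypingSession) -> np.ndarray | None:
    """Per-axis median of the session's accelerometer samples (memoized)."""
    if not hasattr(session, _REP_CACHE):
        if session.accel is None or len(session.accel) == 0:
            rep = None
        else:
            rep = np.median(_xyz(session.accel), axis=0)
        setattr(session, _REP_CACHE, rep)
    return getattr(session, _REP_CACHE)


def is_upright(rep: np.ndarray) -> bool:
    x, _, z = rep
    return bool(UPRIGHT_X[0] <= x <= UPRIGHT_X[1] and z <= UPRIGHT_Z_MAX)


def is_nonupright(rep: np.ndarray) -> bool:
    x, _, z = rep
    return bool((x > NONUPRIGHT_X_ABS or x < -NONUPRIGHT_X_ABS)
                and z >= NONUPRIGHT_Z_MIN)


def fit_orientation_model(
    sessions: list[TypingSession], seed: int = 0,
    candidates=CLUSTER_CANDIDATES,
) -> OrientationModel:
    """Cluster per-session orientation representatives.

    Candidate cluster counts are scored by silhouette; deterministic given
    ``seed``. Fewer than two sessions with accelerometer data degenerate to
    a single-cluster model with a warning.
    """
    reps, sids = [], []
    for s in sessions:
        r = session_representative(s)
        if r is not None:
            reps.append(r)
            sids.append(s.session_id)
    pid = sessions[0].participant_id if sessions else ""
    if len(reps) < 2:
        warnings.warn("fewer than 2 sessions with accel: single-cluster model",
                      stacklevel=2)
        centroid = np.mean(reps, axis=0) if reps else np.zeros(3)
        return OrientationModel(pid, centroid.reshape(1, 3),
                                {s: 0 for s in sids}, 1)
    X = np.asarray(reps)
    kmin = min(candidates)
    if np.allclose(X, X[0]):
        # zero spread: the minimum candidate count with coincident centroids
        return OrientationModel(pid, np.tile(X[0], (kmin, 1)),
                                {s: 0 for s in sids}, kmin)

    best = None
    for k in candidates:
        if k >= len(X) or k > len(np.unique(X, axis=0)):
            continue
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(X, km.labels_)
        if best is None or score > best[0]:
            best = (score, km)
    if best is None:
        km = KMeans(n_clusters=kmin, random_state=seed, n_init=10).fit(X)
    else:
        km = best[1]
    labels = km.predict(X)
    return OrientationModel(
        pid, km.cluster_centers_, dict(zip(sids, labels.tolist())),
        km.cluster_centers_.shape[0],
    )


def _aa_ikds_of_session(session: TypingSession) -> np.ndarray:
    ks = session.keystrokes
    if len(ks) < 2:
        return np.array([])
    cat = ks["key_category"].to_numpy()
    ts = pd.to_datetime(ks["timestamp"]).to_numpy()
    ikd = np.diff(ts).astype("timedelta64[ns]").astype(float) / 1e9
    aa = (cat[:-1] == "alphanumeric") & (cat[1:] == "alphanumeric")
    return ikd[aa]


def compute_typing_features(window_sessions: list[TypingSession]) -> dict:
    """Session counts, key-category rates, typing speed and press durations.

    ``typingSpeed`` is the median alphanumeric->alphanumeric interkey delay
    restricted to two-handed sessions; it is ``None`` (row flagged) when the
    window holds no such session.
    """
    n_sessions = len(window_sessions)
    sizes = np.array([len(s) for s in window_sessions])
    total = int(sizes.sum())
    cats = pd.concat([s.keystrokes["key_category"] for s in window_sessions])
    press = pd.concat([s.keystrokes["press_duration"] for s in window_sessions])

    two_handed_ikds = np.concatenate(
        [_aa_ikds_of_session(s) for s in window_sessions if s.hand_mode == "two"]
        or [np.array([])])
    all_ikds = np.concatenate(
        [_aa_ikds_of_session(s) for s in window_sessions] or [np.array([])])

    return {
        "nSessions": float(n_sessions),
        "avgNkeypresses": float(sizes.mean()) if n_sessions else 0.0,
        "backspaceRate": float((cats == "backspace").sum() / total) if total else 0.0,
        "autocorrectRate": float((cats == "autocorrect").sum() / total) if total else 0.0,
        "typingSpeed": float(np.median(two_handed_ikds)) if len(two_handed_ikds) else None,
        "varAAIKD": float(np.var(all_ikds)) if len(all_ikds) else 0.0,
        "medianPressDuration": float(press.median()) if total else 0.0,
    }


def compute_accel_features(
    window_sessions: list[TypingSession],
    model: OrientationModel,
    prior_week_sessions: list[TypingSession],
    night_window: tuple[int, int] = NIGHT_WINDOW,
) -> dict:
    """Orientation-derived features for a task window.

    Cluster transitions are counted over consecutive window sessions (by
    start time); within-session transitions re-assign each accelerometer
    sample to its nearest centroid.
    """
    ordered = sorted(window_sessions, key=lambda s: s.start)
    reps = [(s, session_representative(s)) for s in ordered]
    with_accel = [(s, r) for s, r in reps if r is not None]

    xs = np.concatenate([s.accel["x"].to_numpy(dtype=float)
                         for s, _ in with_accel] or [np.array([])])
    median_x = float(np.median(np.abs(xs))) if len(xs) else 0.0

    frac_upright = (float(np.mean([is_upright(r) for _, r in with_accel]))
                    if with_accel else 0.0)

    night = []
    for s in prior_week_sessions:
        if night_window[0] <= s.start.hour < night_window[1]:
            r = session_representative(s)
            if r is not None:
                night.append(is_nonupright(r))
    frac_night = float(np.mean(night)) if night else 0.0

    seq = [int(model.assign(r)[0]) for _, r in with_accel]
    n_transitions = int(np.sum(np.asarray(seq[1:]) != np.asarray(seq[:-1]))) if len(seq) > 1 else 0
    norm_transitions = n_transitions / len(ordered) if ordered else 0.0

    per_session = []
    for s, _ in with_accel:
        lab = model.assign(_xyz(s.accel))
        per_session.append(int(np.sum(lab[1:] != lab[:-1])))
    avg_within = float(np.mean(per_session)) if per_session else 0.0

    return {
        "nClusters": float(model.n_clusters),
        "normalized_n_cluster_transitions": float(norm_transitions),
        "avg_n_cluster_transitions_perSession": avg_within,
        "medianX": median_x,
        "fraction_nighttime_nonUpright_sessions": frac_night,
        "fraction_upright": frac_upright,
        "flag_no_nighttime_sessions": not night,
    }


def circular_variance(row: np.ndarray) -> float | None:
    """1 - mean resultant length of hour angles weighted by activity.

    0 = all activity at one hour; 1 = uniform over the day. ``None`` for an
    all-zero row (undefined).
    """
    w = np.asarray(row, dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    angles = 2.0 * np.pi * np.arange(24) / 24.0
    resultant = np.abs(np.sum(w * np.exp(1j * angles))) / total
    return float(1.0 - resultant)


def _cosine(a: np.ndarray, b: np.ndarray) -> float | None:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    return float(np.dot(a, b) / (na * nb))


def compute_regularity_features(
    wstar_rows: np.ndarray, daily_sleep_hours: np.ndarray
) -> dict:
    """Regularity/sleep features from W* rows and sleep quantities of the
    week before a task. All-zero rows are skipped (flagged) in the per-row
    statistics.
    """
    rows = np.atleast_2d(np.asarray(wstar_rows, dtype=float))
    cvs = [cv for cv in (circular_variance(r) for r in rows) if cv is not None]
    skipped = rows.shape[0] - len(cvs)

    def med_cos(gap: int) -> float:
        sims = [s for s in (_cosine(rows[d], rows[d + gap])
                            for d in range(rows.shape[0] - gap)) if s is not None]
        return float(np.median(sims)) if sims else 0.0

    sleep = np.asarray(daily_sleep_hours, dtype=float)
    return {
        "varCircVar": float(np.var(cvs)) if cvs else 0.0,
        "medAmt_noActivity": float(np.median(sleep)) if len(sleep) else 0.0,
        "varAmt_noActivity": float(np.var(sleep)) if len(sleep) else 0.0,
        "medianCosineSimilarity_1diff": med_cos(1),
        "medianCosineSimilarity_4diff": med_cos(4),
        "flag_zero_rows_skipped": skipped,
    }


def center_features(table: pd.DataFrame, feature_columns: list[str] | None = None) -> pd.DataFrame:
    """Expand raw feature columns into ``_gm`` and ``_sc`` variants.

    ``_gm`` is the participant's raw mean (constant within participant,
    uncentered); ``_sc`` is the raw value minus that mean, so every ``_sc``
    column averages to zero within participant and ``gm + sc`` reconstructs
    the raw value exactly.
    """
    if feature_columns is None:
        feature_columns = [c for c in ALL_FEATURES if c in table.columns]
    out = table.copy()
    for col in feature_columns:
        gm = out.groupby("participant_id")[col].transform("mean")
        out[f"{col}_gm"] = gm
        out[f"{col}_sc"] = out[col] - gm
    return out


def candidate_columns(table: pd.DataFrame) -> list[str]:
    """The expanded gm/sc candidate predictor set present in a table."""
    return [f"{c}_{suffix}" for c in ALL_FEATURES for suffix in ("gm", "sc")
            if f"{c}_{suffix}" in table.columns]
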