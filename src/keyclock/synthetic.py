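"""Synthetic cohort generator with planted ground truth.

The study's raw smartphone streams are private, so this module emulates the
statistical structure the pipeline assumes and exposes the planted truth for
recovery tests:

* per-participant circadian keystroke intensity (hour-of-day profile,
  weekend modulation) with a nightly inactivity window of fixed duration
  whose onset jitters from night to night;
* lognormal interkey delays around a participant-level median;
* typing sessions carrying a hand-mode flag and accelerometer samples drawn
  around per-participant phone-orientation centroids with Markov switching
  between sessions;
* trail-making tasks whose completion time decays geometrically with task
  number (practice effect) and loads on latent typing-speed and
  regularity factors;
* PHQ self-reports correlated with a shared latent mood factor, whose
  influence on task times is fully mediated by the speed/regularity latents.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import write_stream

# Hour-of-day intensity template (relative weights, scaled by the
# participant's base rate). Mornings ramp up, evenings peak.
DEFAULT_PROFILE = np.array(
    [0.3, 0.2, 0.2, 0.2, 0.3, 0.4, 0.6, 0.9, 1.0, 1.0, 1.0, 1.1,
     1.2, 1.1, 1.0, 1.0, 1.1, 1.2, 1.3, 1.4, 1.4, 1.2, 0.9, 0.6]
)

# Library of phone orientations in g-units (gravity components while typing).
# The first is upright portrait; the others are reclined/lying postures that
# satisfy the non-upright predicate (|x| > 0.5 and z >= 0.1).
ORIENTATION_LIBRARY = np.array(
    [
        [0.00, -0.90, -0.30],
        [0.70, -0.30, 0.40],
        [-0.70, -0.30, 0.40],
        [0.05, -0.40, -0.85],
    ]
)


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale: 60 participants x 30 days, a planted 8 h
    nightly inactivity window with sub-hour onset jitter, ~10 expected
    keystrokes per waking hour scaled by the circadian profile, and task /
    PHQ models tied to latent speed, regularity and mood factors.
    """

    n_participants: int = 60
    n_days: int = 30
    seed: int = 0
    start_date: str = "2024-01-01"  # a Monday

    # sleep window
    sleep_onset_mean: float = 23.0    # hour of day
    sleep_onset_sd: float = 0.8       # between participants
    sleep_duration_mean: float = 8.0  # hours
    sleep_duration_sd: float = 0.75   # between participants
    sleep_jitter_sd: float = 0.5      # nightly onset jitter (h); scaled by regularity latent
    sleep_jitter_reg_slope: float = 0.25  # extra jitter per SD of the regularity latent

    # circadian intensity
    rate_per_hour: float = 10.0       # expected keystrokes per waking hour (profile mean 1)
    rate_log_sd: float = 0.3          # participant-level lognormal spread of the base rate
    profile: np.ndarray = field(default_factory=lambda: DEFAULT_PROFILE.copy())
    weekend_modulation: float = 1.2   # multiplies weekend-hour intensity

    # interkey delays / keystrokes
    ikd_median: float = 0.22          # seconds, cohort geometric mean
    ikd_log_sd_between: float = 0.25  # participant spread of log median IKD
    ikd_log_sd_within: float = 0.5    # within-participant lognormal dispersion
    press_duration_median: float = 0.083
    press_duration_log_sd: float = 0.3
    backspace_rate: float = 0.12
    autocorrect_rate: float = 0.03
    punctuation_rate: float = 0.08
    special_rate: float = 0.02
    mean_session_keystrokes: int = 40
    p_two_handed: float = 0.85
    p_one_handed: float = 0.10

    # orientation clusters
    min_clusters: int = 2
    max_clusters: int = 3
    orientation_within_sd: float = 0.05  # g
    orientation_transition_prob: float = 0.2
    accel_samples_per_session: int = 5

    # task model: time = baseline * decay^(n-1) * exp(b_s*speed + b_r*reg + noise)
    task_baseline_time: float = 20.0
    task_practice_decay: float = 0.95
    task_beta_speed: float = 0.25
    task_beta_regularity: float = 0.15
    task_noise_sd: float = 0.20
    task_error_rate: float = 1.0      # Poisson mean of n_errors
    task_interval_days: int = 5
    max_tasks: int = 6

    # PHQ model
    phq_mean: float = 6.0
    phq_sd: float = 2.0               # residual SD around the mood effect
    phq_mood_slope: float = 3.0
    phq_interval_days: int = 14

    # latent structure: mood -> speed/regularity loadings
    mood_speed_loading: float = 0.5
    mood_regularity_loading: float = 0.4

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_days <= 0:
            raise ConfigError("n_participants and n_days must be positive")
        if not 1.0 <= self.sleep_duration_mean <= 12.0:
            raise ConfigError("sleep_duration_mean must be within [1, 12] hours")
        for name in ("backspace_rate", "autocorrect_rate", "punctuation_rate",
                     "special_rate", "p_two_handed", "p_one_handed",
                     "orientation_transition_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.backspace_rate + self.autocorrect_rate + self.punctuation_rate + self.special_rate >= 1.0:
            raise ConfigError("key-category rates must sum to < 1")
        if len(self.profile) != 24:
            raise ConfigError("profile must have 24 hourly weights")


@dataclass
class GroundTruth:
    """Planted truth: sleep labels, latent factors, and expected task times."""

    start_date: pd.Timestamp
    participants: pd.DataFrame          # pid, onset, duration, jitter_sd, latents, ikd_median
    sleep_labels: dict[str, np.ndarray]  # pid -> (n_days, 24) uint8, 1 = asleep
    task_expected: pd.DataFrame         # pid, task_number, expected_time

    def label_matrix_for_dates(self, participant_id: str, dates) -> np.ndarray:
        """True sleep labels for the given calendar dates (rows) x 24 hours."""
        full = self.sleep_labels[participant_id]
        out = np.zeros((len(dates), 24), dtype=np.uint8)
        for r, d in enumerate(pd.to_datetime(dates)):
            day = (d.normalize() - self.start_date.normalize()).days
            if 0 <= day < full.shape[0]:
                out[r] = full[day]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "start_date": str(self.start_date.date()),
            "participants": self.participants.to_dict(orient="records"),
            "sleep_labels": {p: m.tolist() for p, m in self.sleep_labels.items()},
            "task_expected": self.task_expected.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            start_date=pd.Timestamp(payload["start_date"]),
            participants=pd.DataFrame(payload["participants"]),
            sleep_labels={p: np.array(m, dtype=np.uint8)
                          for p, m in payload["sleep_labels"].items()},
            task_expected=pd.DataFrame(payload["task_expected"]),
        )


@dataclass
class CohortStreams:
    keystrokes: pd.DataFrame
    accel: pd.DataFrame
    tasks: pd.DataFrame
    phq: pd.DataFrame

    def write(self, outdir: str | Path, fmt: str = "csv") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = "jsonl" if fmt == "jsonl" else "csv"
        for name in ("keystrokes", "accel", "tasks", "phq"):
            write_stream(getattr(self, name), outdir / f"{name}.{ext}")


def _participant_latents(config: CohortConfig, rng: np.random.Generator, n: int):
    """Draw the shared latent structure: mood -> (speed, regularity)."""
    mood = rng.normal(0.0, 1.0, n)
    ls, lr = config.mood_speed_loading, config.mood_regularity_loading
    speed = ls * mood + np.sqrt(max(1 - ls**2, 0.0)) * rng.normal(0, 1, n)
    reg = lr * mood + np.sqrt(max(1 - lr**2, 0.0)) * rng.normal(0, 1, n)
    return mood, speed, reg


def _sleep_coverage(onset_abs: np.ndarray, duration: float, n_hours: int):
    """Per-hour sleep coverage fraction and >=50%-coverage labels.

    ``onset_abs`` holds one absolute onset time (hours since the start of the
    study) per night; each night covers [onset, onset + duration).
    """
    coverage = np.zeros(n_hours)
    for onset in onset_abs:
        lo, hi = onset, onset + duration
        first, last = int(np.floor(lo)), int(np.ceil(hi))
        for h in range(max(first, 0), min(last, n_hours)):
            coverage[h] += max(0.0, min(h + 1, hi) - max(h, lo))
    labels = (coverage >= 0.5).astype(np.uint8)
    return np.clip(coverage, 0.0, 1.0), labels


def _distribute_phq_items(total: int) -> list[int]:
    """Split a PHQ total (0-24) across 8 items, each capped at 3."""
    base, rem = divmod(int(total), 8)
    return [min(base + (1 if k < rem else 0), 3) for k in range(8)]


def generate_cohort(config: CohortConfig) -> tuple[CohortStreams, GroundTruth]:
    """Generate the four record streams plus planted ground truth.

    Hourly keystroke counts are Poisson with intensity
    ``rate * profile[hour] * weekend_factor * (1 - sleep coverage)``, so the
    intensity is exactly zero inside the jittered nightly window. Keystrokes
    arrive in sessions whose interkey delays are lognormal around the
    participant's median; sessions carry hand mode and accelerometer samples
    around the session's orientation centroid.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    start = pd.Timestamp(config.start_date).normalize()
    n_hours = config.n_days * 24

    mood, speed, reg = _participant_latents(config, rng, n)
    pids = [f"P{k:03d}" for k in range(n)]
    onset = rng.normal(config.sleep_onset_mean, config.sleep_onset_sd, n)
    duration = np.clip(
        rng.normal(config.sleep_duration_mean, config.sleep_duration_sd, n), 1.0, 12.0
    )
    jitter_sd = np.clip(
        config.sleep_jitter_sd + config.sleep_jitter_reg_slope * reg, 0.0, 1.0
    )
    ikd_median = config.ikd_median * np.exp(config.ikd_log_sd_between * speed)
    base_rate = config.rate_per_hour * np.exp(rng.normal(0, config.rate_log_sd, n))
    n_clusters = rng.integers(config.min_clusters, config.max_clusters + 1, n)

    cat_probs = np.array([
        1.0 - config.backspace_rate - config.autocorrect_rate
        - config.punctuation_rate - config.special_rate,
        config.backspace_rate, config.autocorrect_rate,
        config.punctuation_rate, config.special_rate,
    ])
    cat_names = np.array(["alphanumeric", "backspace", "autocorrect", "punctuation", "special"])
    hand_probs = np.array([
        config.p_two_handed, config.p_one_handed,
        1.0 - config.p_two_handed - config.p_one_handed,
    ])
    hand_names = np.array(["two", "one", "unknown"])

    weekday = np.array([(start + pd.Timedelta(days=d)).weekday() for d in range(config.n_days)])
    weekend_factor = np.where(weekday >= 5, config.weekend_modulation, 1.0)

    ks_cols: dict[str, list] = {k: [] for k in
                                ("participant_id", "t_sec", "key_category",
                                 "press_duration", "session_id", "hand_mode")}
    ac_cols: dict[str, list] = {k: [] for k in
                                ("participant_id", "session_id", "t_sec", "x", "y", "z")}
    sleep_labels: dict[str, np.ndarray] = {}

    for p in range(n):
        pid = pids[p]
        prng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + p]))

        # include the night before day 0 so the first morning is asleep
        nightly = onset[p] + prng.normal(0.0, jitter_sd[p], config.n_days + 1)
        onset_abs = np.arange(-1, config.n_days) * 24.0 + nightly
        coverage, labels = _sleep_coverage(onset_abs, duration[p], n_hours)
        sleep_labels[pid] = labels.reshape(config.n_days, 24)

        lam = (base_rate[p]
               * np.tile(config.profile, config.n_days)
               * np.repeat(weekend_factor, 24)
               * (1.0 - coverage.reshape(config.n_days, 24).reshape(-1)))
        counts = prng.poisson(lam)

        centroids = (ORIENTATION_LIBRARY[:n_clusters[p]]
                     + prng.normal(0, 0.03, (n_clusters[p], 3)))
        cluster_state = int(prng.integers(n_clusters[p]))

        for cell in np.flatnonzero(counts):
            n_keys = int(counts[cell])
            day, hour = divmod(int(cell), 24)
            # place sessions inside the waking portion of the hour
            wake_frac = 1.0 - coverage[cell]
            n_sess = max(1, int(round(n_keys / config.mean_session_keystrokes)))
            sizes = np.maximum(prng.multinomial(n_keys - n_sess, np.full(n_sess, 1 / n_sess)) + 1, 1)
            starts = np.sort(prng.uniform(0.0, max(wake_frac - 0.05, 0.01), n_sess)) * 3600.0
            for s_idx, (sz, s_off) in enumerate(zip(sizes, starts)):
                sid = f"{pid}-d{day}h{hour}s{s_idx}"
                ikds = prng.lognormal(np.log(ikd_median[p]), config.ikd_log_sd_within, sz)
                t0 = cell * 3600.0 + s_off
                tsec = t0 + np.concatenate(([0.0], np.cumsum(ikds[1:])))
                cats = cat_names[prng.choice(5, sz, p=cat_probs)]
                press = prng.lognormal(np.log(config.press_duration_median),
                                       config.press_duration_log_sd, sz)
                hand = hand_names[prng.choice(3, p=hand_probs)]
                ks_cols["participant_id"].append(np.full(sz, pid, dtype=object))
                ks_cols["t_sec"].append(tsec)
                ks_cols["key_category"].append(cats)
                ks_cols["press_duration"].append(press)
                ks_cols["session_id"].append(np.full(sz, sid, dtype=object))
                ks_cols["hand_mode"].append(np.full(sz, hand, dtype=object))
                # orientation Markov chain across sessions
                if prng.random() < config.orientation_transition_prob and n_clusters[p] > 1:
                    others = [c for c in range(n_clusters[p]) if c != cluster_state]
                    cluster_state = int(prng.choice(others))
                na = config.accel_samples_per_session
                samp = centroids[cluster_state] + prng.normal(0, config.orientation_within_sd, (na, 3))
                at = t0 + np.linspace(0.0, float(tsec[-1] - t0), na)
                ac_cols["participant_id"].append(np.full(na, pid, dtype=object))
                ac_cols["session_id"].append(np.full(na, sid, dtype=object))
                ac_cols["t_sec"].append(at)
                ac_cols["x"].append(samp[:, 0])
                ac_cols["y"].append(samp[:, 1])
                ac_cols["z"].append(samp[:, 2])

    def _stack(cols: dict[str, list]) -> pd.DataFrame:
        data = {k: np.concatenate(v) if v else np.array([]) for k, v in cols.items()}
        df = pd.DataFrame(data)
        df["timestamp"] = start + pd.to_timedelta(df.pop("t_sec"), unit="s")
        return df

    keystrokes = _stack(ks_cols).sort_values(
        ["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    accel = _stack(ac_cols).sort_values(
        ["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    keystrokes = keystrokes[["participant_id", "timestamp", "key_category",
                             "press_duration", "session_id", "hand_mode"]]
    accel = accel[["participant_id", "session_id", "timestamp", "x", "y", "z"]]

    participants = pd.DataFrame({
        "participant_id": pids,
        "sleep_onset": onset,
        "sleep_duration": duration,
        "sleep_jitter_sd": jitter_sd,
        "latent_mood": mood,
        "latent_speed": speed,
        "latent_regularity": reg,
        "ikd_median": ikd_median,
    })
    truth = GroundTruth(
        start_date=start,
        participants=participants,
        sleep_labels=sleep_labels,
        task_expected=pd.DataFrame(columns=["participant_id", "task_number", "expected_time"]),
    )

    tasks = generate_tasks(config, truth)
    phq = _generate_phq(config, truth)
    return CohortStreams(keystrokes, accel, tasks, phq), truth


def generate_tasks(config: CohortConfig, latent: GroundTruth) -> pd.DataFrame:
    """Generate dTMT-B records with a geometric practice decay.

    ``completion_time = baseline * decay^(task_number - 1)
    * exp(beta_s * speed + beta_r * regularity + noise)``; the noiseless
    expectation is recorded in ``latent.task_expected``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rows, expected = [], []
    start = latent.start_date
    for _, pr in latent.participants.iterrows():
        pid = pr["participant_id"]
        effect = (config.task_beta_speed * pr["latent_speed"]
                  + config.task_beta_regularity * pr["latent_regularity"])
        day = 2
        number = 0
        while day < config.n_days and number < config.max_tasks:
            number += 1
            hour = 14.0 + rng.uniform(-2.0, 2.0)
            ts = start + pd.Timedelta(days=day) + pd.Timedelta(hours=hour)
            mean_time = (config.task_baseline_time
                         * config.task_practice_decay ** (number - 1)
                         * np.exp(effect))
            t = mean_time * np.exp(rng.normal(0.0, config.task_noise_sd))
            rows.append({
                "participant_id": pid,
                "timestamp": ts,
                "completion_time": float(t),
                "n_errors": int(rng.poisson(config.task_error_rate)),
                "layout_variant": int(rng.integers(1, 13)),
            })
            expected.append({"participant_id": pid, "task_number": number,
                             "expected_time": float(mean_time)})
            day += config.task_interval_days
    latent.task_expected = pd.DataFrame(expected)
    return pd.DataFrame(rows)


def _generate_phq(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 8]))
    rows = []
    for _, pr in truth.participants.iterrows():
        for day in range(1, config.n_days, config.phq_interval_days):
            total = int(np.clip(round(
                config.phq_mean + config.phq_mood_slope * pr["latent_mood"]
                + rng.normal(0.0, config.phq_sd)), 0, 24))
            items = _distribute_phq_items(total)
            row = {"participant_id": pr["participant_id"],
                   "timestamp": truth.start_date + pd.Timedelta(days=day, hours=12)}
            row.update({f"item_{k+1}": items[k] for k in range(8)})
            row["total"] = total
            rows.append(row)
    return pd.DataFrame(rows)
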