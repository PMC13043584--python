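"""Feature engineering: orientation model, typing/accel/regularity features,
gm/sc centering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_session
from keyclock.features import (ALL_FEATURES, OrientationModel,
                               candidate_columns, center_features,
                               circular_variance, compute_accel_features,
                               compute_regularity_features,
                               compute_typing_features, fit_orientation_model,
                               is_nonupright, is_upright)


def _orientation_sessions(rng, centroids, n_per=12, sd=0.02):
    sessions, labels = [], []
    t = pd.Timestamp("2024-01-02 10:00:00")
    for k in range(n_per):
        for c, centroid in enumerate(centroids):
            pts = np.asarray(centroid) + rng.normal(0, sd, (5, 3))
            sessions.append(make_session(
                session_id=f"s{k}-{c}", start=t, accel_xyz=pts))
            labels.append(c)
            t += pd.Timedelta(minutes=30)
    return sessions, labels


def test_two_separated_orientation_groups_are_recovered():
    rng = np.random.default_rng(0)
    sessions, labels = _orientation_sessions(
        rng, [(0.0, -0.9, -0.3), (0.8, -0.9, -0.3)])  # 0.8 g apart
    model = fit_orientation_model(sessions, seed=1)
    assert model.n_clusters == 2
    assigned = np.array([model.assignments[s.session_id] for s in sessions])
    # assignment matches generation up to label permutation
    same = assigned == np.array(labels)
    assert same.all() or (~same).all()


def test_identical_sessions_degenerate_to_minimum_candidate():
    pts = np.tile([0.0, -0.9, -0.3], (5, 1))
    sessions = [make_session(session_id=f"s{k}", accel_xyz=pts)
                for k in range(6)]
    model = fit_orientation_model(sessions, seed=0)
    assert model.n_clusters == 2
    assert np.allclose(model.centroids[0], model.centroids[1])


def test_orientation_model_deterministic_given_seed():
    rng = np.random.default_rng(3)
    sessions, _ = _orientation_sessions(
        rng, [(0.0, -0.9, -0.3), (0.8, -0.9, -0.3), (-0.7, -0.2, 0.4)], n_per=8)
    m1 = fit_orientation_model(sessions, seed=5)
    m2 = fit_orientation_model(sessions, seed=5)
    assert m1.n_clusters == m2.n_clusters
    np.testing.assert_allclose(m1.centroids, m2.centroids)
    assert m1.assignments == m2.assignments


def test_single_session_warns_single_cluster():
    s = make_session(accel_xyz=[(0.1, -0.8, 0.0)])
    with pytest.warns(UserWarning, match="single-cluster"):
        model = fit_orientation_model([s])
    assert model.n_clusters == 1


@pytest.mark.parametrize("rep,upright,nonupright", [
    ((0.1, -0.3, 0.05), True, False),
    ((0.6, 0.1, 0.2), False, True),
    ((0.0, -0.9, 0.5), False, False),   # vertical x but z up: neither
    ((-0.7, 0.0, 0.05), False, False),  # tilted but z below bound
])
def test_posture_predicates(rep, upright, nonupright):
    rep = np.asarray(rep)
    assert is_upright(rep) is upright
    assert is_nonupright(rep) is nonupright


def test_typing_features_rates_and_medians():
    cats = ["alphanumeric"] * 8 + ["backspace"] * 2
    s1 = make_session(session_id="a", ikds=[0.1, 0.2, 0.3] + [0.2] * 6,
                      categories=cats, hand_mode="two")
    out = compute_typing_features([s1])
    assert out["nSessions"] == 1
    assert out["avgNkeypresses"] == 10
    assert out["backspaceRate"] == pytest.approx(0.2)
    assert out["autocorrectRate"] == 0.0
    assert out["medianPressDuration"] == pytest.approx(0.08)
    # first three IKDs are the only AA transitions before the backspaces:
    # delays 0.1, 0.2, 0.3, 0.2 ... median over AA pairs
    assert out["typingSpeed"] == pytest.approx(np.median([0.1, 0.2, 0.3, 0.2, 0.2, 0.2, 0.2]))


def test_typing_speed_requires_two_handed_sessions():
    one = make_session(hand_mode="one", ikds=[0.2, 0.2])
    out = compute_typing_features([one])
    assert out["typingSpeed"] is None
    assert out["varAAIKD"] == pytest.approx(0.0)  # equal IKDs


def test_cluster_transition_counting():
    a, b = (0.0, -0.9, -0.3), (0.8, -0.9, -0.3)
    seq = [a, a, b, a]
    sessions = [make_session(session_id=f"s{k}", start=f"2024-01-02 1{k}:00:00",
                             accel_xyz=np.tile(c, (4, 1)))
                for k, c in enumerate(seq)]
    model = OrientationModel("P0", np.array([a, b]), {}, 2)
    out = compute_accel_features(sessions, model, prior_week_sessions=[])
    assert out["normalized_n_cluster_transitions"] == pytest.approx(2 / 4)
    assert out["avg_n_cluster_transitions_perSession"] == 0.0
    assert out["nClusters"] == 2.0


def test_nighttime_nonupright_fraction_uses_prior_week_night_sessions():
    model = OrientationModel("P0", np.array([[0.0, -0.9, -0.3]]), {}, 1)
    night_flat = make_session(session_id="n1", start="2024-01-02 02:00:00",
                              accel_xyz=np.tile([0.7, -0.2, 0.4], (4, 1)))
    night_up = make_session(session_id="n2", start="2024-01-03 01:00:00",
                            accel_xyz=np.tile([0.0, -0.9, -0.2], (4, 1)))
    day_flat = make_session(session_id="d", start="2024-01-03 15:00:00",
                            accel_xyz=np.tile([0.7, -0.2, 0.4], (4, 1)))
    out = compute_accel_features([], model, [night_flat, night_up, day_flat])
    assert out["fraction_nighttime_nonUpright_sessions"] == pytest.approx(0.5)
    none = compute_accel_features([], model, [day_flat])
    assert none["fraction_nighttime_nonUpright_sessions"] == 0.0
    assert none["flag_no_nighttime_sessions"]


def test_circular_variance_extremes():
    one_hour = np.zeros(24); one_hour[3] = 5.0
    assert circular_variance(one_hour) == pytest.approx(0.0)
    assert circular_variance(np.ones(24)) == pytest.approx(1.0)
    assert circular_variance(np.zeros(24)) is None


def test_identical_rows_give_unit_cosine_and_zero_varcircvar():
    row = np.zeros(24); row[8:20] = 1.0
    rows = np.tile(row, (6, 1))
    out = compute_regularity_features(rows, daily_sleep_hours=[8, 8, 8, 8, 8, 8])
    assert out["medianCosineSimilarity_1diff"] == pytest.approx(1.0)
    assert out["medianCosineSimilarity_4diff"] == pytest.approx(1.0)
    assert out["varCircVar"] == pytest.approx(0.0)
    assert out["medAmt_noActivity"] == 8.0
    assert out["varAmt_noActivity"] == 0.0


def test_all_zero_rows_are_skipped_with_flag():
    row = np.zeros(24); row[8:20] = 1.0
    rows = np.vstack([row, np.zeros(24), row])
    out = compute_regularity_features(rows, daily_sleep_hours=[8, 8, 8])
    assert out["flag_zero_rows_skipped"] == 1


def test_centering_reconstructs_and_sums_to_zero():
    table = pd.DataFrame({
        "participant_id": ["A", "A", "B"],
        "typingSpeed": [1.0, 3.0, 5.0],
    })
    out = center_features(table, ["typingSpeed"])
    assert out["typingSpeed_gm"].tolist() == [2.0, 2.0, 5.0]
    assert out["typingSpeed_sc"].tolist() == [-1.0, 1.0, 0.0]
    np.testing.assert_allclose(out["typingSpeed_gm"] + out["typingSpeed_sc"],
                               out["typingSpeed"])


def test_candidate_set_has_36_columns(pipeline_run):
    table = pipeline_run.feature_table
    cand = candidate_columns(table)
    assert len(cand) == 2 * len(ALL_FEATURES) == 36


def test_sc_columns_average_to_zero_within_participant(pipeline_run):
    table = pipeline_run.feature_table
    for col in [c for c in candidate_columns(table) if c.endswith("_sc")]:
        per = table.groupby("participant_id")[col].mean().dropna()
        np.testing.assert_allclose(per, 0.0, atol=1e-10)
        assert abs(table[col].dropna().mean()) < 1e-10


def test_rates_and_fractions_stay_in_unit_interval(pipeline_run):
    table = pipeline_run.feature_table
    for col in ("backspaceRate", "autocorrectRate", "fraction_upright",
                "fraction_nighttime_nonUpright_sessions"):
        assert table[col].between(0, 1).all()
    sims = table[["medianCosineSimilarity_1diff", "medianCosineSimilarity_4diff"]]
    assert ((sims >= -1 - 1e-12) & (sims <= 1 + 1e-12)).all().all()
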