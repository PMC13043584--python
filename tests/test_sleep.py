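"""Sleep labeling: binarization, flood fill, extension, cleanup, one-block.

Flood-fill results are checked against an independent connected-component
oracle (scipy.ndimage.label with a 4-connected structuring element).
"""

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage

from keyclock.sleep import (binarize, enforce_single_blocks,
                            extend_pre_midnight, flood_fill_inactive,
                            hour_agreement, single_block_violations,
                            smooth_labels)

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def component_oracle(binary):
    """Zero-component containing the least-active column's earliest zero."""
    labeled, _ = scipy.ndimage.label(binary == 0, structure=FOUR_CONN)
    hour = int(np.argmin(binary.mean(axis=0)))
    day = int(np.flatnonzero(binary[:, hour] == 0)[0])
    return labeled == labeled[day, hour]


def _dates(n):
    return pd.date_range("2024-01-02", periods=n, freq="D")


def test_binarize_threshold_semantics():
    eps = 1e-6
    w = np.array([[0.0, eps / 2, 2 * eps]])
    np.testing.assert_array_equal(binarize(w, eps), [[0, 0, 1]])
    assert binarize(np.full((2, 3), 1.0), eps).all()
    assert not binarize(np.zeros((2, 3)), eps).any()


def test_flood_fill_rectangle_connects_across_days():
    binary = np.ones((5, 24), dtype=np.uint8)
    binary[:, 1:7] = 0
    mask = flood_fill_inactive(binary)
    expected = np.zeros_like(binary, dtype=bool)
    expected[:, 1:7] = True
    np.testing.assert_array_equal(mask, expected)
    np.testing.assert_array_equal(mask, component_oracle(binary))


def test_flood_fill_excludes_isolated_zero():
    binary = np.ones((3, 24), dtype=np.uint8)
    binary[0:2, 1:7] = 0
    binary[0, 15] = 0  # isolated afternoon gap
    mask = flood_fill_inactive(binary)
    assert not mask[0, 15]
    np.testing.assert_array_equal(mask, component_oracle(binary))


def test_flood_fill_single_day_is_a_horizontal_run():
    binary = np.ones((1, 24), dtype=np.uint8)
    binary[0, 2:6] = 0
    binary[0, 10] = 0
    mask = flood_fill_inactive(binary)
    assert mask[0, 2:6].all()
    assert not mask[0, 10]


def test_flood_fill_matches_component_oracle_on_random_grids():
    rng = np.random.default_rng(0)
    for _ in range(30):
        binary = (rng.random((6, 24)) < 0.6).astype(np.uint8)
        if not (binary == 0).any():
            continue
        np.testing.assert_array_equal(flood_fill_inactive(binary),
                                      component_oracle(binary))


def test_flood_fill_all_active_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="no zero cells"):
        mask = flood_fill_inactive(np.ones((3, 24), dtype=np.uint8))
    assert not mask.any()


def test_pre_midnight_extension_walks_back_through_zeros():
    binary = np.ones((2, 24), dtype=np.uint8)
    binary[1, 0:7] = 0
    binary[0, 22:24] = 0
    mask = np.zeros_like(binary, dtype=bool)
    mask[1, 0:7] = True
    out = extend_pre_midnight(mask, binary)
    assert out[0, 22] and out[0, 23]
    assert not out[0, 21]


def test_pre_midnight_extension_requires_masked_midnight():
    binary = np.zeros((2, 24), dtype=np.uint8)
    mask = np.zeros_like(binary, dtype=bool)
    mask[1, 3:7] = True  # block does not touch hour 0
    out = extend_pre_midnight(mask, binary)
    np.testing.assert_array_equal(out, mask)


def test_pre_midnight_extension_stops_at_first_active_hour():
    binary = np.zeros((2, 24), dtype=np.uint8)
    binary[0, 23] = 1
    mask = np.zeros_like(binary, dtype=bool)
    mask[1, 0:5] = True
    out = extend_pre_midnight(mask, binary)
    assert not out[0].any()


def test_label_smoothing_fills_small_gap_and_keeps_large():
    two_gap = np.array([1, 1, 0, 0, 1, 1], dtype=np.uint8)
    np.testing.assert_array_equal(smooth_labels(two_gap), np.ones(6))
    three_gap = np.array([1, 1, 0, 0, 0, 1, 1, 1], dtype=np.uint8)
    np.testing.assert_array_equal(smooth_labels(three_gap), three_gap)


def test_label_smoothing_collapses_alternation_and_is_idempotent():
    seq = np.array([1, 0] * 8, dtype=np.uint8)
    once = smooth_labels(seq)
    twice = smooth_labels(once)
    np.testing.assert_array_equal(once, twice)
    interior = once[2:-2]
    assert len(np.unique(interior)) == 1


def test_single_blocks_keeps_longest_run():
    labels = np.zeros(48, dtype=np.uint8)
    labels[25:32] = 1  # 7 h block in day 2
    labels[40:41] = 1  # 1 h intruder in the same relative day
    m = enforce_single_blocks(labels, _dates(2))
    assert single_block_violations(m) == 0
    assert 7 in m.daily_sleep_hours
    assert m.labels.reshape(-1)[40] == 0


def test_single_block_spanning_midnight_is_counted_once():
    labels = np.zeros(48, dtype=np.uint8)
    labels[20:28] = 1  # 20:00 day 1 .. 04:00 day 2
    m = enforce_single_blocks(labels, _dates(2))
    assert single_block_violations(m) == 0
    assert list(m.daily_sleep_hours) == [8]


def test_no_sleep_run_warns_and_reports_zero():
    with pytest.warns(UserWarning, match="no sleep"):
        m = enforce_single_blocks(np.zeros(48, dtype=np.uint8), _dates(2))
    assert all(h == 0 for h in m.daily_sleep_hours)


def test_one_block_invariant_on_random_labelings():
    rng = np.random.default_rng(1)
    for _ in range(50):
        raw = (rng.random(8 * 24) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        seq = smooth_labels(raw)
        m = enforce_single_blocks(seq, _dates(8))
        assert single_block_violations(m) == 0
        assert ((m.daily_sleep_hours >= 0) & (m.daily_sleep_hours <= 24)).all()


def test_hour_agreement_is_fraction_of_matching_cells():
    a = np.zeros((2, 24)); b = np.zeros((2, 24)); b[0, :12] = 1
    assert hour_agreement(a, b) == pytest.approx(1 - 12 / 48)


def test_hour_aligned_planted_windows_are_recovered():
    """With hour-aligned onsets the pipeline recovers sleep up to the
    one-hour boundary smear of the smoothing graph (>= 90% agreement)."""
    import warnings
    from keyclock import matrices, smoothing
    from keyclock.sleep import estimate_sleep
    from keyclock.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_participants=5, n_days=16, seed=21,
                       sleep_onset_mean=23.0, sleep_onset_sd=0.0,
                       sleep_duration_mean=8.0, sleep_duration_sd=0.0,
                       sleep_jitter_sd=0.0, sleep_jitter_reg_slope=0.0)
    streams, truth = generate_cohort(cfg)
    agreements = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, ks in streams.keystrokes.groupby("participant_id"):
            counts, speed = matrices.build_matrices(ks)
            counts, speed = matrices.apply_week_filters(counts, speed)
            res, _ = smoothing.smooth_participant(counts, speed)
            labels = estimate_sleep(res, counts.dates, pid)
            tl = truth.label_matrix_for_dates(pid, counts.dates)
            agreements.append(hour_agreement(labels.labels, tl))
    assert np.mean(np.asarray(agreements) >= 0.90) >= 0.9
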