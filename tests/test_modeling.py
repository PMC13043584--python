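"""Modeling: subject-wise split, MI selection, tuned fits, metrics,
attribution, and the paired sign-flip permutation test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.linear_model import LinearRegression

from keyclock.modeling import (DEFAULT_GRIDS, FittedModel, ModelReport,
                               ModelingConfig, SplitError, SplitPlan,
                               attribute, evaluate, fit_models,
                               permutation_test_residuals, phq_experiment,
                               run_modeling, select_features_mi, split_cohort)

RF_ONLY = ModelingConfig(grids={"rf": {"criterion": ["squared_error"],
                                       "max_depth": [3], "min_samples_leaf": [4],
                                       "min_samples_split": [3],
                                       "n_estimators": [15]}},
                         models=("rf",))


def _table(n_participants=10, tasks_per=4, seed=0, signal=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        x1 = rng.normal()
        for _ in range(tasks_per):
            x2 = rng.normal()
            rows.append({"participant_id": f"P{p:02d}", "f1": x1,
                         "f2": x2, "f3": rng.normal(),
                         "adjusted_time": signal * x1 + 0.1 * rng.normal()})
    return pd.DataFrame(rows)


def test_split_is_deterministic_disjoint_and_balanced():
    table = _table(10, 4)
    plan1 = split_cohort(table, seed=3)
    plan2 = split_cohort(table, seed=3)
    assert plan1.test_participants == plan2.test_participants
    assert not set(plan1.train_participants) & set(plan1.test_participants)
    assert plan1.participant_fraction == pytest.approx(0.2)
    assert plan1.task_fraction == pytest.approx(0.2)


def test_split_overlap_is_rejected():
    with pytest.raises(SplitError):
        SplitPlan(["A", "B"], ["B"], 0.2, 0.2)
    with pytest.raises(SplitError):
        split_cohort(_table(3, 2))


def test_mi_ranks_copy_of_target_first_and_noise_near_zero():
    rng = np.random.default_rng(1)
    n = 2000
    y = rng.normal(0, 1, n)
    table = pd.DataFrame({"participant_id": "P", "copy": y,
                          "noise": rng.normal(0, 1, n), "adjusted_time": y})
    selected, mi = select_features_mi(table, ["copy", "noise"], k=1, seed=0)
    assert selected == ["copy"]
    assert mi["copy"] > 10 * max(mi["noise"], 1e-6)
    assert mi["noise"] < 0.05


def test_mi_returns_exactly_k_names():
    rng = np.random.default_rng(2)
    cols = {f"c{k:02d}": rng.normal(0, 1, 200) for k in range(36)}
    table = pd.DataFrame({"participant_id": "P", **cols,
                          "adjusted_time": rng.normal(0, 1, 200)})
    selected, _ = select_features_mi(table, list(cols), k=10, seed=0)
    assert len(selected) == 10


def test_fewer_candidates_than_k_warns_and_returns_all():
    table = _table(6, 3)
    with pytest.warns(UserWarning, match="candidates"):
        selected, _ = select_features_mi(table, ["f1", "f2"], k=10, seed=0)
    assert selected == ["f1", "f2"]


def test_fit_models_is_deterministic_and_grids_include_printed_optima():
    assert 0.5 in DEFAULT_GRIDS["lasso"]["model__alpha"]
    assert 0.5 in DEFAULT_GRIDS["svr"]["model__C"]
    assert "poly" in DEFAULT_GRIDS["svr"]["model__kernel"]
    assert 30 in DEFAULT_GRIDS["knn"]["model__n_neighbors"]
    assert "absolute_error" in DEFAULT_GRIDS["rf"]["criterion"]
    assert {15, 30} <= set(DEFAULT_GRIDS["rf"]["n_estimators"])

    table = _table(10, 4)
    cfg = ModelingConfig(grids={"rf": {"max_depth": [2, 4], "n_estimators": [10]}},
                         models=("rf",))
    f1 = fit_models(table, ["f1", "f2"], cfg, seed=5)
    f2 = fit_models(table, ["f1", "f2"], cfg, seed=5)
    assert f1["rf"].best_params == f2["rf"].best_params
    np.testing.assert_allclose(f1["rf"].estimator.predict(table[["f1", "f2"]]),
                               f2["rf"].estimator.predict(table[["f1", "f2"]]))


def test_overpenalized_lasso_predicts_a_constant():
    table = _table(10, 4, signal=0.01)
    cfg = ModelingConfig(grids={"lasso": {"model__alpha": [50.0]}},
                         models=("lasso",))
    fitted = fit_models(table, ["f1", "f2", "f3"], cfg, seed=0)
    preds = fitted["lasso"].estimator.predict(table[["f1", "f2", "f3"]])
    assert np.ptp(preds) == pytest.approx(0.0, abs=1e-12)


def test_evaluate_metric_arithmetic():
    table = _table(10, 2, seed=3)
    fitted = fit_models(table, ["f1"], RF_ONLY, seed=0)
    # exact predictions -> zero error
    perfect = ModelReport("x", {}, 0, 0, 1, 1, pd.DataFrame())
    report = evaluate(fitted["baseline_mean"], table)
    y = table["adjusted_time"].to_numpy()
    assert report.rmse == pytest.approx(
        np.sqrt(np.mean((y - y.mean()) ** 2)))
    assert report.r2 == pytest.approx(0.0, abs=1e-12)  # mean predictor on own rows
    del perfect

    resid = pd.DataFrame({"participant_id": "P", "y_true": [1.0, 2.0],
                          "y_pred": [0.0, 0.0]})
    rep = ModelReport("m", {}, 0, 0, 0, 0, resid)
    err = np.abs(resid.y_true - resid.y_pred)
    assert np.sqrt((err ** 2).mean()) == pytest.approx(np.sqrt(2.5))
    assert err.mean() == pytest.approx(1.5)


def test_attribution_constant_model_is_all_zero():
    table = _table(8, 3)

    class Const:
        def predict(self, X):
            return np.full(len(X), 2.5)

    fm = FittedModel("const", Const(), {}, ["f1", "f2", "f3"])
    out = attribute(fm, table)
    np.testing.assert_allclose(out["attributions"].to_numpy(), 0.0, atol=1e-12)
    assert out["base_value"] == pytest.approx(2.5)


def test_attribution_single_feature_linear_model_gets_all_credit():
    table = _table(8, 3)
    lin = LinearRegression().fit(table[["f1", "f2"]].assign(f2=0.0),
                                 3.0 * table["f1"])
    fm = FittedModel("lin", lin, {}, ["f1", "f2"])
    out = attribute(fm, table)
    assert out["ranking"].index[0] == "f1"
    assert out["ranking"]["f2"] == pytest.approx(0.0, abs=1e-10)
    # additivity: rows sum to prediction - base value
    pred = lin.predict(table[["f1", "f2"]])
    np.testing.assert_allclose(out["attributions"].sum(axis=1),
                               pred - out["base_value"], atol=1e-8)


def test_attribution_ranks_strong_effect_above_weak():
    rng = np.random.default_rng(6)
    table = pd.DataFrame({"participant_id": "P",
                          "A": rng.normal(0, 1, 120),
                          "B": rng.normal(0, 1, 120)})
    table["adjusted_time"] = 5.0 * table["A"] + 0.3 * table["B"]
    lin = LinearRegression().fit(table[["A", "B"]], table["adjusted_time"])
    out = attribute(FittedModel("lin", lin, {}, ["A", "B"]), table)
    assert list(out["ranking"].index) == ["A", "B"]


def _report_from_residuals(res, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, len(res))
    return ModelReport("m", {}, 0, 0, 0, 0, pd.DataFrame(
        {"participant_id": "P", "y_true": y, "y_pred": y - res}))


def test_permutation_test_identical_models_give_p_one():
    rep = _report_from_residuals(np.random.default_rng(0).normal(0, 1, 50))
    assert permutation_test_residuals(rep, rep, n_perm=500, seed=1) == 1.0


def test_permutation_test_detects_planted_improvement():
    rng = np.random.default_rng(2)
    base = np.abs(rng.normal(0, 1, 200)) + 1.0
    rep_a = _report_from_residuals(base + 1.0, seed=3)
    rep_b = _report_from_residuals(base, seed=4)
    assert permutation_test_residuals(rep_a, rep_b, n_perm=999, seed=5) < 0.01


def test_run_modeling_end_to_end_disjoint_and_recomputable():
    table = _table(12, 4, seed=7)
    out = run_modeling(table, ["f1", "f2", "f3"], RF_ONLY, seed=1)
    plan = out["split"]
    assert not set(plan.train_participants) & set(plan.test_participants)
    rep = out["reports"]["rf"]
    y, yhat = rep.predictions["y_true"], rep.predictions["y_pred"]
    assert rep.rmse == pytest.approx(float(np.sqrt(((y - yhat) ** 2).mean())),
                                     abs=1e-12)
    assert rep.mae == pytest.approx(float((y - yhat).abs().mean()), abs=1e-12)


def test_phq_experiment_noise_score_ranks_low_and_base_is_reproducible():
    table = _table(12, 4, seed=8)
    rng = np.random.default_rng(8)
    phq = pd.DataFrame({
        "participant_id": np.repeat(table["participant_id"].unique(), 2),
        "total": rng.integers(0, 20, 24)})
    plan = split_cohort(table, seed=2)
    out = phq_experiment(table, phq, ["f1", "f2"], plan, RF_ONLY, seed=2)
    # PHQ is pure noise here: it must not dominate the attribution ranking
    ranking = out["augmented_ranking"]
    assert ranking.index[0] != "avgPHQ"
    # the no-PHQ control model matches an independent fit on the same split
    train = table[table["participant_id"].isin(plan.train_participants)]
    test = table[table["participant_id"].isin(plan.test_participants)]
    control = evaluate(fit_models(train, ["f1", "f2"], RF_ONLY, seed=2)["rf"], test)
    assert control.rmse == pytest.approx(out["base"].rmse)
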