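"""Two-stage hurdle model: threshold selection, smearing, composition,
determinism, and the pluggable learner contract."""

import numpy as np
import pandas as pd
import pytest

import effortcast as ec
from effortcast.features import FeatureSchema
from effortcast.hurdle import (HurdleSpec, encoded_width, hyperparameter_grid,
                               threshold_candidates)
from effortcast.metrics import f1_score_binary
from effortcast.panel import FoldPlan


def _brute_force_best_f1(probs, labels):
    cands = np.unique(np.concatenate([[0.0], probs, [1.0]]))
    best = max(f1_score_binary(labels, probs >= c) for c in cands)
    return best


def _numeric_schema(names):
    return FeatureSchema(groups=("residual",), kinds={n: "numeric" for n in names},
                         categorical_levels={}, lag_floor=0.0, no_mpa_distance_m=0.0)


def _fold_frame(X, y_occ, y_log, years):
    df = X.copy()
    df["outcome_occurrence"] = y_occ
    df["outcome_hours"] = np.where(y_occ == 1, np.exp(y_log), 0.0)
    df["outcome_log"] = np.where(y_occ == 1, y_log, np.nan)
    df["outcome_year"] = years
    df["pixel_id"] = np.arange(len(df))
    return df


def test_smearing_coefficient_values():
    assert ec.smearing_coefficient([0.0, 0.0, 0.0]) == 1.0
    assert ec.smearing_coefficient([np.log(2), np.log(0.5)]) == pytest.approx(1.25)
    rng = np.random.default_rng(0)
    r = rng.normal(0.0, 0.5, 10_000)
    # lognormal moment: E[e^eps] = exp(sigma^2 / 2) = exp(0.125)
    assert ec.smearing_coefficient(r) == pytest.approx(np.exp(0.125), rel=0.02)
    with pytest.raises(ValueError):
        ec.smearing_coefficient([])


def test_threshold_candidates_reach_every_confusion_matrix():
    probs = np.array([0.9, 0.8, 0.3, 0.2])
    cands = threshold_candidates(probs)
    assert cands[0] < probs.min() and cands[-1] > probs.max()
    labels = np.array([1, 1, 0, 1])
    f1s = {c: f1_score_binary(labels, probs >= c) for c in cands}
    # all-positive classification achieves F1 = 6/7, beating 0.8 at tau=0.55
    assert max(f1s.values()) == pytest.approx(6 / 7)
    assert f1s[0.55] == pytest.approx(0.8)
    best_tau = min(c for c, v in f1s.items() if v == max(f1s.values()))
    assert best_tau < 0.2


def test_selected_threshold_matches_brute_force_scan_on_random_sets():
    rng = np.random.default_rng(7)
    for _ in range(50):
        probs = np.round(rng.random(25), 2)
        labels = rng.integers(0, 2, 25)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        cands = threshold_candidates(probs)
        best = max(f1_score_binary(labels, probs >= c) for c in cands)
        assert best == pytest.approx(_brute_force_best_f1(probs, labels), abs=1e-12)


def test_select_threshold_on_separable_synthetic_folds():
    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=(n, 2))
    y = (x[:, 0] + x[:, 1] > 0).astype(int)
    X = pd.DataFrame(x, columns=["f1", "f2"])
    ylog = 1.0 + 0.5 * x[:, 0]
    years = np.repeat([2018, 2019], n // 2)
    df = _fold_frame(X, y, ylog, years)
    schema = _numeric_schema(["f1", "f2"])
    plan = FoldPlan(folds=[([2018], 2019)])
    spec = HurdleSpec(learner="linear", seed=0)
    tau = ec.select_threshold(df, plan, spec, schema, None)
    assert 0.0 < tau < 1.0


def test_tuning_prefers_signal_over_degenerate_combination():
    """A grid with a degenerate combination (1 feature, huge node size) never
    beats a full-signal combination when the classes need both features."""
    rng = np.random.default_rng(9)
    n = 400
    x = rng.normal(size=(n, 2))
    y = ((x[:, 0] > 0) ^ (x[:, 1] > 0)).astype(int)  # XOR: needs both features
    X = pd.DataFrame(x, columns=["f1", "f2"])
    df = _fold_frame(X, y, np.ones(n), np.repeat([2018, 2019], n // 2))
    schema = _numeric_schema(["f1", "f2"])
    plan = FoldPlan(folds=[([2018], 2019)])
    spec = HurdleSpec(n_trees=100, seed=1)
    import effortcast.hurdle as hmod
    grid = [{"mtry": 1, "min_n": 200}, {"mtry": 2, "min_n": 2}]
    orig = hmod.hyperparameter_grid
    hmod.hyperparameter_grid = lambda *a, **k: grid
    try:
        best = ec.tune_stage1(df, plan, spec, schema)
    finally:
        hmod.hyperparameter_grid = orig
    assert best == {"mtry": 2, "min_n": 2}


def test_lhs_grid_has_ten_points_in_range():
    spec = HurdleSpec(seed=4)
    grid = hyperparameter_grid(spec, 60)
    assert len(grid) == 10
    for g in grid:
        assert 1 <= g["mtry"] <= 60
        assert 2 <= g["min_n"] <= 40
    assert hyperparameter_grid(spec, 60) == grid  # seeded determinism


@pytest.fixture(scope="module")
def linear_fit():
    """Simple-learner hurdle on a generator whose stage-2 truth is linear."""
    rng = np.random.default_rng(11)
    n = 5000
    x = rng.normal(size=(n, 3))
    beta = np.array([0.8, -0.5, 0.3])
    logit = 1.0 + x[:, 0]
    y_occ = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    y_log = -2.0 + x @ beta + rng.normal(0, 0.4, n)
    X = pd.DataFrame(x, columns=["f1", "f2", "f3"])
    df = _fold_frame(X, y_occ, y_log, np.repeat([2017, 2018, 2019, 2020], n // 4))
    schema = _numeric_schema(["f1", "f2", "f3"])
    plan = FoldPlan(folds=[([2017], 2018), ([2018], 2019), ([2019], 2020)])
    model = ec.fit_hurdle(df, plan, HurdleSpec(learner="linear", seed=0), schema)
    return model, df, beta


def test_simple_learner_contract_runs_end_to_end(linear_fit):
    model, df, _ = linear_fit
    hours = model.predict_hours(df, np.ones(len(df)))
    assert (hours >= 0).all()
    assert model.smear > 0 and 0 < model.tau < 1


def test_linear_stage2_recovers_true_slopes_within_ten_percent(linear_fit):
    model, _, beta = linear_fit
    coefs = model.stage2.named_steps["model"].coef_
    np.testing.assert_allclose(coefs, beta, rtol=0.10)


def test_stage2_trains_only_on_positive_rows(linear_fit):
    model, df, _ = linear_fit
    pos = int((df["outcome_hours"] > 0).sum())
    # refit and compare against a manual positive-only fit
    assert model.stage2.named_steps["model"].coef_.shape[0] == 3
    from sklearn.linear_model import LinearRegression
    ref = LinearRegression().fit(df.loc[df["outcome_hours"] > 0, ["f1", "f2", "f3"]],
                                 df.loc[df["outcome_hours"] > 0, "outcome_log"])
    np.testing.assert_allclose(model.stage2.named_steps["model"].coef_, ref.coef_,
                               atol=1e-9)
    assert pos == (df["outcome_occurrence"] == 1).sum()


def test_composition_identity_rowwise(linear_fit):
    model, df, _ = linear_fit
    areas = np.linspace(0.5, 2.0, len(df))
    hours = model.predict_hours(df, areas)
    p = model.predict_proba(df)
    yhat = model.predict_log(df)
    np.testing.assert_allclose(
        hours, (p >= model.tau) * model.smear * np.exp(yhat) * areas, rtol=1e-12)
    assert (hours[p < model.tau] == 0).all()


def test_doubling_smear_doubles_positive_predictions(linear_fit):
    model, df, _ = linear_fit
    h1 = model.predict_hours(df, np.ones(len(df)))
    import copy
    m2 = copy.copy(model)
    m2.smear = 2 * model.smear
    h2 = m2.predict_hours(df, np.ones(len(df)))
    np.testing.assert_allclose(h2, 2 * h1)


def test_refit_with_same_seed_is_deterministic():
    rng = np.random.default_rng(2)
    n = 300
    x = rng.normal(size=(n, 2))
    y = (x[:, 0] > 0).astype(int)
    df = _fold_frame(pd.DataFrame(x, columns=["f1", "f2"]), y,
                     0.5 * x[:, 1], np.repeat([2018, 2019], n // 2))
    schema = _numeric_schema(["f1", "f2"])
    plan = FoldPlan(folds=[([2018], 2019)])
    spec = HurdleSpec(n_trees=50, seed=13)
    m1 = ec.fit_hurdle(df, plan, spec, schema)
    m2 = ec.fit_hurdle(df, plan, spec, schema)
    probe = df.sample(30, random_state=0)
    np.testing.assert_array_equal(m1.predict_hours(probe, np.ones(30)),
                                  m2.predict_hours(probe, np.ones(30)))
    assert m1.tau == m2.tau and m1.smear == m2.smear


def test_schema_hash_guard_and_missing_features(linear_fit):
    model, df, _ = linear_fit
    with pytest.raises(ValueError, match="hash"):
        model.check_schema("deadbeef")
    with pytest.raises(ValueError, match="missing"):
        model.predict_proba(df.drop(columns=["f2"]))


def test_hurdle_beats_single_stage_on_zero_inflated_data():
    """With >= 30% structural zeros, the hurdle's level-scale rsq_trad
    exceeds a single regressor trained with zeros included."""
    rng = np.random.default_rng(21)
    n = 4000
    x = rng.normal(size=(n, 3))
    p_occ = 1 / (1 + np.exp(-6.0 * (x[:, 0] + 0.4)))  # sharply structural zeros
    y_occ = (rng.random(n) < p_occ).astype(int)
    y_log = 0.5 + 0.9 * x[:, 1] + rng.normal(0, 0.4, n)
    X = pd.DataFrame(x, columns=["f1", "f2", "f3"])
    df = _fold_frame(X, y_occ, y_log, np.repeat([2017, 2018, 2019, 2020], n // 4))
    assert (df["outcome_hours"] == 0).mean() > 0.3
    train = df[df["outcome_year"] < 2020]
    test = df[df["outcome_year"] == 2020]
    plan = FoldPlan(folds=[([2017], 2018), ([2018], 2019)])
    schema = _numeric_schema(["f1", "f2", "f3"])
    model = ec.fit_hurdle(train, plan, HurdleSpec(learner="linear", seed=0), schema)
    hurdle_pred = model.predict_hours(test, np.ones(len(test)))

    from sklearn.linear_model import LinearRegression
    single = LinearRegression().fit(train[["f1", "f2", "f3"]], train["outcome_hours"])
    single_pred = np.clip(single.predict(test[["f1", "f2", "f3"]]), 0, None)

    y_level = test["outcome_hours"].values
    assert ec.rsq_trad(y_level, hurdle_pred) > ec.rsq_trad(y_level, single_pred)


def test_model_bundle_round_trips_through_directory(linear_fit, tmp_path):
    model, df, _ = linear_fit
    model.save(tmp_path / "bundle")
    back = ec.FittedHurdle.load(tmp_path / "bundle")
    probe = df.sample(20, random_state=1)
    np.testing.assert_allclose(back.predict_hours(probe, np.ones(20)),
                               model.predict_hours(probe, np.ones(20)))
    assert back.tau == model.tau and back.schema_hash == model.schema_hash
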