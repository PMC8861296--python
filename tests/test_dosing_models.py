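import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from vancodose.dosing_models import (
    DEFAULT_HYPERPARAMS,
    DOSE_FLOOR,
    PKBaselineParams,
    RecommenderConfig,
    assert_patient_disjoint,
    explain,
    pk_baseline,
    recommend,
    train,
    tune,
)
from vancodose.features import FeatureMatrix
from vancodose.labeling import DoseRecord

T0 = pd.Timestamp("2019-01-01 08:00")
FAST_HP = dict(DEFAULT_HYPERPARAMS, n_estimator=80, m_depth=4)


def toy_matrix(X: pd.DataFrame, y, mode="subsequent", pid_prefix="P") -> FeatureMatrix:
    records = [
        DoseRecord(f"{pid_prefix}{i}", T0, 1000.0, is_initial=(mode == "initial"))
        for i in range(len(y))
    ]
    return FeatureMatrix(X=X, y=pd.Series(y, dtype=float), manifest=list(X.columns),
                         mode=mode, records=records)


def planted_weight_matrices(rng, n=400):
    """target = 30 · weight exactly; other columns are noise."""
    def make(n, prefix):
        X = pd.DataFrame(
            {
                "weight_kg": rng.uniform(40, 110, n),
                "age_years": rng.uniform(20, 90, n),
                "noise": rng.normal(0, 1, n),
            }
        )
        return toy_matrix(X, 30.0 * X["weight_kg"].to_numpy(), pid_prefix=prefix)
    return make(n, "A"), make(n // 4, "B")


def test_constant_labels_predict_that_constant(rng):
    X = pd.DataFrame({"x": rng.normal(0, 1, 50)})
    m = toy_matrix(X, np.full(50, 2000.0))
    fitted = train(m, FAST_HP, seed=0)
    assert recommend(fitted, m.X) == pytest.approx(np.full(50, 2000.0))


def test_planted_signal_is_recovered(rng):
    tm, vm = planted_weight_matrices(rng)
    fitted = train(tm, FAST_HP, seed=0)
    preds = recommend(fitted, vm.X)
    mae = np.abs(preds - vm.y.to_numpy()).mean()
    assert mae < 0.05 * vm.y.mean()
    assert "weight_kg" in fitted.importances.index[:3]


def test_all_missing_column_warns_but_trains(rng):
    X = pd.DataFrame({"x": rng.normal(0, 1, 40), "empty": np.nan})
    m = toy_matrix(X, rng.uniform(1000, 3000, 40))
    with pytest.warns(UserWarning, match="empty"):
        fitted = train(m, FAST_HP, seed=0)
    assert fitted.manifest == ["x", "empty"]


def test_non_positive_targets_rejected(rng):
    X = pd.DataFrame({"x": rng.normal(0, 1, 10)})
    m = toy_matrix(X, np.linspace(-1, 2000, 10))
    with pytest.raises(ValueError):
        train(m, FAST_HP, seed=0)


def test_recommend_is_deterministic_and_floored(rng):
    tm, vm = planted_weight_matrices(rng, n=120)
    fitted = train(tm, FAST_HP, seed=3)
    a = recommend(fitted, vm.X)
    b = recommend(fitted, vm.X)
    assert np.array_equal(a, b)
    assert (a >= DOSE_FLOOR).all()
    single = recommend(fitted, vm.X.iloc[0].to_dict())
    assert single == pytest.approx(a[0])


def test_recommend_rejects_manifest_mismatch(rng):
    tm, vm = planted_weight_matrices(rng, n=60)
    fitted = train(tm, FAST_HP, seed=0)
    with pytest.raises(ValueError, match="manifest"):
        recommend(fitted, vm.X.drop(columns=["noise"]))


def test_retraining_same_seed_is_bit_identical(rng):
    tm, vm = planted_weight_matrices(rng, n=200)
    p1 = recommend(train(tm, FAST_HP, seed=9), vm.X)
    p2 = recommend(train(tm, FAST_HP, seed=9), vm.X)
    assert np.array_equal(p1, p2)


# ---------------------------------------------------------------------------
# tuning

def test_grid_of_size_one_returns_that_combination(rng):
    tm, vm = planted_weight_matrices(rng, n=80)
    combo = dict(DEFAULT_HYPERPARAMS, n_estimator=123, m_depth=3)
    cfg = RecommenderConfig(
        bayes_evals=0, seed=0, hyperparameters=dict(combo),
        grid={k: [v] for k, v in combo.items()},
    )
    best = tune(tm, vm, cfg)
    assert best == combo
    assert set(best) == set(DEFAULT_HYPERPARAMS)


def test_strictly_better_grid_point_wins(rng):
    tm, vm = planted_weight_matrices(rng, n=150)
    # severely underfit starting point vs a reasonable grid candidate
    cfg = RecommenderConfig(
        bayes_evals=0, seed=0,
        hyperparameters=dict(DEFAULT_HYPERPARAMS, n_estimator=1),
        grid={"n_estimator": [1, 200], "learning_rate": [0.1]},
    )
    best = tune(tm, vm, cfg)
    assert best["n_estimator"] == 200


def test_tuning_deterministic_given_seed(rng):
    tm, vm = planted_weight_matrices(rng, n=80)
    cfg = lambda: RecommenderConfig(bayes_evals=6, seed=21, grid={})
    assert tune(tm, vm, cfg()) == tune(tm, vm, cfg())


def test_tune_requires_patient_disjoint_and_nonempty(rng):
    tm, _ = planted_weight_matrices(rng, n=40)
    with pytest.raises(ValueError):
        tune(tm, replace(tm, y=tm.y.iloc[:0], X=tm.X.iloc[:0],
                         records=[]), RecommenderConfig(bayes_evals=1))
    with pytest.raises(ValueError, match="more than one split"):
        assert_patient_disjoint(tm, tm)


# ---------------------------------------------------------------------------
# PK baseline

def test_proportional_adjustment_closed_form():
    dose = pk_baseline(70, 100.0, False, last_daily_dose=2000, observed_trough=8.5)
    assert dose == pytest.approx(2000 * 17 / 8.5)  # = 4000


def test_on_target_trough_keeps_dose():
    assert pk_baseline(70, 100.0, False, last_daily_dose=2000,
                       observed_trough=17.0) == pytest.approx(2000)


def test_hd_initial_rule_20mg_per_kg_per_48h():
    daily = pk_baseline(80, None, True)
    assert daily == pytest.approx(20 * 80 * 24 / 48)  # 1600 mg/event q48h


def test_subsequent_baseline_monotone_and_linear():
    troughs = np.linspace(5, 30, 10)
    doses = [pk_baseline(70, 80.0, False, last_daily_dose=2000, observed_trough=t)
             for t in troughs]
    assert all(a >= b for a, b in zip(doses, doses[1:]))  # decreasing in trough
    d1 = pk_baseline(70, 80.0, False, last_daily_dose=1000, observed_trough=10)
    d2 = pk_baseline(70, 80.0, False, last_daily_dose=2000, observed_trough=10)
    assert d2 == pytest.approx(2 * d1)  # linear in last dose


def test_subsequent_baseline_clipped():
    assert pk_baseline(70, 80.0, False, last_daily_dose=5000,
                       observed_trough=2.0) == 6000.0
    assert pk_baseline(70, 80.0, False, last_daily_dose=300,
                       observed_trough=30.0) == 250.0


def test_invalid_observed_trough_rejected():
    with pytest.raises(ValueError):
        pk_baseline(70, 80.0, False, last_daily_dose=2000, observed_trough=0.0)


def test_initial_inversion_hits_target_trough():
    """The recommended dose drives the model trough to exactly 17."""
    from vancodose.synthetic_data import steady_state_trough

    p = PKBaselineParams()
    daily = pk_baseline(70, 100.0, False, params=p)
    cl, v = 6.0, 0.7 * 70
    assert steady_state_trough(daily, p.interval_h, cl, v, p.infusion_h) == \
        pytest.approx(p.target_trough)


# ---------------------------------------------------------------------------
# attributions

def test_attributions_sum_to_prediction(rng):
    tm, vm = planted_weight_matrices(rng, n=150)
    fitted = train(tm, FAST_HP, seed=0)
    contrib = explain(fitted, vm.X)
    raw = fitted.model.predict(vm.X[fitted.manifest])
    np.testing.assert_allclose(contrib.sum(axis=1), raw, rtol=1e-6)


def test_planted_signal_dominates_attributions(rng):
    tm, vm = planted_weight_matrices(rng)
    fitted = train(tm, FAST_HP, seed=0)
    contrib = explain(fitted, vm.X).drop(columns="base")
    top = contrib.abs().mean().idxmax()
    assert top == "weight_kg"


def test_stump_model_attributes_to_split_feature(rng):
    X = pd.DataFrame({"a": rng.uniform(0, 1, 200), "b": rng.uniform(0, 1, 200)})
    y = np.where(X["a"] > 0.5, 3000.0, 1000.0)
    m = toy_matrix(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = train(m, dict(FAST_HP, m_depth=1, n_estimator=30), seed=0)
    contrib = explain(fitted, X).drop(columns="base").abs().mean()
    assert contrib["a"] > 10 * max(contrib["b"], 1e-9)
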