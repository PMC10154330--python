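"""Stacking, meta-learner and base-model filtering tests."""

import numpy as np
import pandas as pd
import pytest

from pepsl.super_learner import (
    BaseModelSpec, EnsembleModel, HoldoutMatrix, default_zoo,
    filter_base_models, fit_meta_learner, fit_super_learner,
    make_holdout_predictions, select_classification_threshold,
)

SMALL_ZOO = [
    BaseModelSpec("glm", "generalized-linear"),
    BaseModelSpec("rf", "random-forest", (("n_estimators", 30),)),
    BaseModelSpec("gbm", "gradient-boosting",
                  (("n_estimators", 50), ("max_depth", 2))),
]


def _toy_regression(rng, n=120, p=6):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"v{j}" for j in range(p)])
    y = 2 * X["v0"].to_numpy() - X["v1"].to_numpy() + 0.3 * rng.standard_normal(n)
    return X, y


# ---------------------------------------------------------------------------
# holdout predictions


def test_holdout_shape_and_fold_partition(rng):
    X, y = _toy_regression(rng)
    hold = make_holdout_predictions(SMALL_ZOO, X, y, "regression", seed=0)
    assert hold.predictions.shape == (len(y), len(SMALL_ZOO))
    assert sorted(np.unique(hold.fold_of)) == list(range(10))


def test_overfitter_holdout_differs_from_resubstitution(rng):
    """A single fully grown tree memorizes the training data, so its
    resubstitution predictions track y exactly while holdout ones cannot."""
    X, y = _toy_regression(rng, n=100)
    spec = BaseModelSpec("xrt1", "extremely-randomized-trees",
                         (("n_estimators", 1),))
    hold = make_holdout_predictions([spec], X, y, "regression", seed=1)
    from pepsl.super_learner import build_estimator
    est = build_estimator(spec, "regression", seed=1).fit(X.to_numpy(), y)
    resub = est.predict(X.to_numpy())
    assert np.allclose(resub, y)  # memorized (unbootstrapped pure-leaf tree)
    assert np.mean((hold.predictions["xrt1"] - y) ** 2) > 100 * np.mean(
        (resub - y) ** 2 + 1e-12)


def test_failing_model_column_dropped(rng, caplog):
    X, y = _toy_regression(rng)
    bad = BaseModelSpec("bad", "gradient-boosting", (("learning_rate", -1.0),))
    with caplog.at_level("WARNING"):
        hold = make_holdout_predictions(SMALL_ZOO + [bad], X, y,
                                        "regression", seed=0)
    assert "bad" not in hold.model_ids
    assert len(hold.model_ids) == len(SMALL_ZOO)
    assert any("bad" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# meta-learner


def test_perfect_base_model_gets_unit_weight(rng):
    y = rng.standard_normal(60) + 5
    H = pd.DataFrame({"perfect": y, "noise": rng.standard_normal(60)})
    hm = HoldoutMatrix(H, np.arange(60) % 10, "regression")
    mf = fit_meta_learner(hm, y, seed=0)
    assert mf.weights["perfect"] == pytest.approx(1.0, abs=1e-6)
    assert mf.intercept == pytest.approx(0.0, abs=1e-6)
    assert (mf.coef_matrix.loc["perfect"] > 0.99).all()
    assert mf.coef_matrix.shape == (2, 10)


def test_duplicate_columns_share_weight_predictions_unchanged(rng):
    y = rng.standard_normal(80)
    col = 0.8 * y + 0.2 * rng.standard_normal(80)
    single = HoldoutMatrix(pd.DataFrame({"a": col}), np.arange(80) % 10,
                           "regression")
    double = HoldoutMatrix(pd.DataFrame({"a": col, "b": col}),
                           np.arange(80) % 10, "regression")
    mf1 = fit_meta_learner(single, y, seed=0)
    mf2 = fit_meta_learner(double, y, seed=0)
    assert mf2.weights.sum() == pytest.approx(mf1.weights.sum(), abs=1e-8)
    np.testing.assert_allclose(
        mf1.predict(single.predictions), mf2.predict(double.predictions),
        atol=1e-8)


def test_meta_learner_weights_nonnegative(rng):
    y = rng.standard_normal(50)
    H = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
    mf = fit_meta_learner(HoldoutMatrix(H, np.arange(50) % 10, "regression"),
                          y, seed=0)
    assert (mf.weights >= 0).all()
    assert (mf.coef_matrix >= 0).to_numpy().all()


def test_meta_learner_needs_enough_rows(rng):
    H = pd.DataFrame({"a": rng.standard_normal(5)})
    with pytest.raises(ValueError):
        fit_meta_learner(HoldoutMatrix(H, np.arange(5), "regression"),
                         rng.standard_normal(5))


# ---------------------------------------------------------------------------
# iterative filtering


def _fn_from_tables(tables):
    """coeff_fn backed by a dict mapping frozenset(ids) -> DataFrame."""
    def fn(ids):
        return tables[frozenset(ids)]
    return fn


def test_filtering_fixed_point_when_all_nonzero():
    coefs = pd.DataFrame(np.ones((3, 10)), index=list("ABC"))
    survivors, log = filter_base_models(
        _fn_from_tables({frozenset("ABC"): coefs}), list("ABC"))
    assert survivors == list("ABC")
    assert len(log) == 1 and log[0]["removed"] == []


def test_filtering_removes_mostly_zero_model():
    full = pd.DataFrame(np.ones((3, 10)), index=list("ABC"))
    full.loc["A", :6] = 0.0  # 7 zero folds > 5
    refit = pd.DataFrame(np.ones((2, 10)), index=list("BC"))
    survivors, log = filter_base_models(
        _fn_from_tables({frozenset("ABC"): full, frozenset("BC"): refit}),
        list("ABC"))
    assert survivors == ["B", "C"]
    assert log[0]["removed"] == ["A"] and log[1]["removed"] == []


def test_filtering_cascade_two_iterations():
    full = pd.DataFrame(np.ones((3, 10)), index=list("ABC"))
    full.loc["A", :6] = 0.0
    refit1 = pd.DataFrame(np.ones((2, 10)), index=list("BC"))
    refit1.loc["B", :5] = 0.0  # removing A drives B to 6 zero folds
    refit2 = pd.DataFrame(np.ones((1, 10)), index=list("C"))
    survivors, log = filter_base_models(
        _fn_from_tables({frozenset("ABC"): full, frozenset("BC"): refit1,
                         frozenset("C"): refit2}), list("ABC"))
    assert survivors == ["C"]
    assert [it["removed"] for it in log] == [["A"], ["B"], []]
    assert len(log) <= 3  # terminates in <= n iterations


def test_filtering_can_empty_the_zoo():
    zeros = pd.DataFrame(np.zeros((2, 10)), index=list("AB"))
    survivors, log = filter_base_models(
        _fn_from_tables({frozenset("AB"): zeros}), list("AB"))
    assert survivors == []


# ---------------------------------------------------------------------------
# threshold selection


def test_threshold_perfect_separation():
    t = select_classification_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
    assert t == 0.6  # the only candidate threshold reaching F1 = 1


def test_threshold_degenerate_equal_scores():
    t = select_classification_threshold([0.5, 0.5, 0.5], [0, 1, 1])
    assert t == 0.5  # all-positive call


def test_threshold_requires_both_classes():
    with pytest.raises(ValueError):
        select_classification_threshold([0.2, 0.8], [1, 1])


# ---------------------------------------------------------------------------
# full super learner


def test_super_learner_end_to_end_regression(rng):
    X, y = _toy_regression(rng, n=150)
    model = fit_super_learner(SMALL_ZOO, X, y, "regression", seed=0)
    assert 1 <= model.survivor_count <= len(SMALL_ZOO)
    # prediction is exactly the meta-learner applied to base predictions
    H = model.base_predictions(X)
    manual = H[model.weights.index].to_numpy() @ model.weights.to_numpy() \
        + model.intercept
    np.testing.assert_allclose(model.predict(X), manual, rtol=0, atol=1e-12)


def test_super_learner_reproducible(rng):
    X, y = _toy_regression(rng, n=120)
    zoo = SMALL_ZOO[:2]
    m1 = fit_super_learner(zoo, X, y, "regression", seed=5)
    m2 = fit_super_learner(zoo, X, y, "regression", seed=5)
    pd.testing.assert_series_equal(m1.weights, m2.weights)
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


def test_super_learner_classification_threshold_and_proba(rng):
    n = 150
    X = pd.DataFrame(rng.standard_normal((n, 5)),
                     columns=[f"v{j}" for j in range(5)])
    y = (X["v0"].to_numpy() + 0.4 * rng.standard_normal(n) > 0).astype(int)
    model = fit_super_learner(SMALL_ZOO, X, y, "classification", seed=1)
    assert model.threshold is not None
    proba = model.predict_proba(X)
    assert proba.shape == (n, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    labels = model.predict_label(X)
    assert set(labels) <= {0, 1}
    assert np.mean(labels == y) > 0.8


def test_homogeneous_filter_and_empty_error(rng):
    X, y = _toy_regression(rng, n=100)
    model = fit_super_learner(SMALL_ZOO, X, y, "regression",
                              homogeneous="generalized-linear", seed=0)
    assert all(s.family == "generalized-linear" for s in model.specs)
    with pytest.raises(ValueError):
        fit_super_learner(SMALL_ZOO, X, y, "regression",
                          homogeneous="neural-network", seed=0)


def test_save_load_roundtrip(tmp_path, rng):
    X, y = _toy_regression(rng, n=100)
    model = fit_super_learner(SMALL_ZOO[:2], X, y, "regression", seed=2)
    model.save(tmp_path / "model")
    loaded = EnsembleModel.load(tmp_path / "model")
    np.testing.assert_allclose(loaded.predict(X), model.predict(X))


def test_default_zoo_families_and_ids():
    zoo = default_zoo("regression", seed=0, n_grid=2)
    ids = [s.id for s in zoo]
    assert len(ids) == len(set(ids))
    assert {"generalized-linear", "random-forest",
            "extremely-randomized-trees", "gradient-boosting",
            "extreme-gradient-boosting", "neural-network"} == \
        {s.family for s in zoo}
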