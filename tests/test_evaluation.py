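"""Split plans, metrics, rank-sum selection and nested-CV leakage tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from pepsl.evaluation import (
    Candidate, adversarial_control, bedroc, compute_metrics,
    enrichment_factor, make_nested_splits, rank_and_select,
    run_nested_evaluation,
)


# ---------------------------------------------------------------------------
# split plans


def test_modulo_inner_fold_sizes():
    # 25-sample training set over 10 modulo folds: 5 folds of 3, 5 of 2
    plan = make_nested_splits(30, outer=1, inner=10, test_fraction=5 / 30,
                              seed=0)
    train = plan.outer[0][0]
    sizes = [len(test) for _, test in plan.inner[0]]
    assert len(train) == 25
    assert sizes == [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]


def test_outer_splits_partition_and_inner_partition_training_set():
    plan = make_nested_splits(57, outer=10, inner=10, test_fraction=0.2, seed=3)
    for (train, test), inner in zip(plan.outer, plan.inner):
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == 57
        covered = np.concatenate([t for _, t in inner])
        assert sorted(covered) == sorted(train)
        for itr, ite in inner:
            assert set(itr) | set(ite) == set(train)
            assert not set(itr) & set(ite)


def test_split_plan_seeding():
    a = make_nested_splits(40, seed=1)
    b = make_nested_splits(40, seed=1)
    c = make_nested_splits(40, seed=2)
    assert all(np.array_equal(x[1], y[1]) for x, y in zip(a.outer, b.outer))
    assert any(not np.array_equal(x[1], y[1]) for x, y in zip(a.outer, c.outer))


def test_split_plan_rejects_empty_test():
    with pytest.raises(ValueError):
        make_nested_splits(20, test_fraction=0.01)


# ---------------------------------------------------------------------------
# metrics


def test_perfect_predictions_metrics():
    reg = compute_metrics("regression", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert reg["r2"] == 1.0 and reg["pct_mae"] == 0.0 and reg["pct_rmse"] == 0.0
    y = np.array([0, 0, 1, 1])
    clf = compute_metrics("classification", y, np.array([0.01, 0.02, 0.98, 0.99]),
                          ef_fraction=0.25)
    assert clf["mcc"] == 1.0 and clf["f1"] == 1.0
    assert clf["balanced_accuracy"] == 1.0
    assert clf["log_loss"] < 0.05
    assert clf["bedroc"] == pytest.approx(1.0, abs=1e-6)


def test_mcc_from_stated_confusion_table():
    # TP=50, TN=45, FP=5, FN=0
    truth = np.array([1] * 50 + [0] * 50)
    pred = np.array([1.0] * 50 + [1.0] * 5 + [0.0] * 45)
    m = compute_metrics("classification", truth, pred, ef_fraction=0.5)
    assert m["mcc"] == pytest.approx(0.9045, abs=1e-4)


def test_random_scores_give_null_metrics():
    rng = np.random.default_rng(42)
    y = rng.integers(0, 2, size=2000)
    scores = rng.uniform(size=2000)
    m = compute_metrics("classification", y, scores, ef_fraction=0.1)
    assert abs(m["mcc"]) < 0.07
    t = rng.standard_normal(2000)
    r = compute_metrics("regression", t, rng.standard_normal(2000))
    assert r["r2"] < 0.07  # out-of-signal R^2 is near or below zero


def test_zero_truth_range_rejected():
    with pytest.raises(ValueError):
        compute_metrics("regression", [1.0, 1.0], [1.0, 2.0])


def test_bedroc_early_recognition():
    labels = np.array([1] * 5 + [0] * 95)
    perfect = -np.arange(100.0)
    assert bedroc(labels, perfect) == pytest.approx(1.0, abs=1e-6)
    assert bedroc(labels, np.arange(100.0)) < 0.05


def test_enrichment_factor_anchor():
    labels = np.array([1] * 5 + [0] * 95)
    assert enrichment_factor(labels, -np.arange(100.0), 0.05) == pytest.approx(20.0)
    assert enrichment_factor(labels, np.arange(100.0), 0.05) == 0.0


# ---------------------------------------------------------------------------
# rank-sum selection


def _fold_df(rows):
    return pd.DataFrame(rows, columns=["r2", "pct_mae"])


def test_identical_models_all_competitive(rng):
    folds = _fold_df(rng.uniform(size=(10, 2)))
    sel = rank_and_select({"a": folds, "b": folds.copy(), "c": folds.copy()})
    assert (sel.p_values == 1.0).all().all()
    assert sorted(sel.competitive) == ["a", "b", "c"]
    assert sel.top_model in sel.competitive


def test_dominated_model_excluded(rng):
    good = _fold_df(np.column_stack([
        0.8 + 0.01 * rng.standard_normal(10),
        5 + 0.1 * rng.standard_normal(10)]))
    bad = _fold_df(np.column_stack([
        0.2 + 0.01 * rng.standard_normal(10),
        20 + 0.1 * rng.standard_normal(10)]))
    sel = rank_and_select({"good": good, "bad": bad})
    assert sel.top_model == "good"
    assert "bad" not in sel.competitive


def test_rank_tie_broken_by_id():
    a = _fold_df(np.column_stack([np.full(4, 0.9), np.full(4, 10.0)]))
    b = _fold_df(np.column_stack([np.full(4, 0.5), np.full(4, 5.0)]))
    # a wins r2 (rank 1 vs 2), b wins pct_mae: equal rank sums
    sel = rank_and_select({"mB": b, "mA": a})
    assert sel.scores["mA"] == sel.scores["mB"]
    assert sel.tie_broken and sel.top_model == "mA"


def test_bh_adjustment_monotone(rng):
    models = {
        f"m{i}": _fold_df(np.column_stack([
            (0.5 + 0.05 * i) + 0.02 * rng.standard_normal(10),
            10 - 0.3 * i + 0.05 * rng.standard_normal(10)]))
        for i in range(5)
    }
    sel = rank_and_select(models)
    raw = sel.p_values.to_numpy().ravel()
    adj = sel.adjusted_p.to_numpy().ravel()
    order = np.argsort(raw)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj >= raw - 1e-12).all()


# ---------------------------------------------------------------------------
# nested evaluation


def _reg_candidates():
    return [
        Candidate("ridge", lambda s: Ridge(alpha=1.0)),
        Candidate("rf", lambda s: RandomForestRegressor(
            n_estimators=30, random_state=s, n_jobs=1)),
    ]


def test_nested_evaluation_recovers_oracle_r2(planted_regression):
    """Outer-loop R^2 should approach the planted signal fraction."""
    X, y, info = planted_regression
    plan = make_nested_splits(len(y), outer=10, inner=10, test_fraction=0.2,
                              seed=3)
    report = run_nested_evaluation(_reg_candidates(), X, y, "regression",
                                   plan, seed=1)
    assert len(report.per_split) == 10
    assert abs(report.mean("r2") - info["oracle_r2"]) < 0.1
    assert all(sid in {"ridge", "rf"} for sid in report.selected_ids)
    assert set(report.summary.index) == {"r2", "pct_mae", "pct_rmse"}


def test_no_leakage_from_outer_test_responses(planted_regression):
    """Poisoning the outer test responses must not change the fitted models
    or their test predictions (only the reported metrics)."""
    X, y, _ = planted_regression
    plan = make_nested_splits(len(y), outer=1, inner=10, test_fraction=0.2,
                              seed=5)
    clean = run_nested_evaluation(_reg_candidates(), X, y, "regression",
                                  plan, seed=2)
    y_poisoned = np.asarray(y, dtype=float).copy()
    test_idx = plan.outer[0][1]
    y_poisoned[test_idx] = np.random.default_rng(0).normal(1e3, 1e2,
                                                           size=len(test_idx))
    poisoned = run_nested_evaluation(_reg_candidates(), X, y_poisoned,
                                     "regression", plan, seed=2)
    assert clean.per_split[0]["selected"] == poisoned.per_split[0]["selected"]
    np.testing.assert_array_equal(clean.per_split[0]["test_predictions"],
                                  poisoned.per_split[0]["test_predictions"])
    assert clean.per_split[0]["metrics"] != poisoned.per_split[0]["metrics"]


def test_adversarial_control_preserves_label_multiset(planted_classification):
    X, y, _ = planted_classification
    rng = np.random.default_rng(7)
    shuffled = rng.permutation(y)
    assert sorted(shuffled) == sorted(y)
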