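"""Nested cross-validation, metrics, rank-sum model selection and
adversarial controls.

The outer loop draws 10 Monte Carlo train/test splits; within each outer
training set the inner loop assigns folds by the modulo of the
within-training positional index.  Inner-loop fold metrics select the top
model by rank-sum score; Mann–Whitney U tests against the top model (BH
adjusted) identify the competitive set.  The outer loop retrains the
selected model per split and aggregates test metrics into the
generalization estimate.  An adversarial control reruns the identical
machinery on permuted responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import f1_score, log_loss, matthews_corrcoef
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: metric -> True if larger is better
METRIC_ORIENTATION = {
    "r2": True, "pct_mae": False, "pct_rmse": False,
    "log_loss": False, "mcc": True, "f1": True,
    "balanced_accuracy": True, "ef": True, "bedroc": True,
}

REGRESSION_METRICS = ("r2", "pct_mae", "pct_rmse")
CLASSIFICATION_METRICS = ("log_loss", "mcc", "f1", "balanced_accuracy",
                          "ef", "bedroc")


@dataclass(frozen=True)
class SplitPlan:
    """Outer Monte Carlo splits with modulo-assigned inner folds.

    ``outer[s]`` is a (train, test) index pair; ``inner[s][f]`` is a
    (train, test) pair of indices *into the full data set* partitioning the
    s-th outer training set.
    """

    outer: tuple
    inner: tuple
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer)


def make_nested_splits(
    n: int, outer: int = 10, inner: int = 10,
    test_fraction: float = 0.2, seed: int = 0,
    shuffle_inner: bool = False,
) -> SplitPlan:
    """Build the nested split plan.

    Outer splits hold out ``test_fraction`` by seeded sampling without
    replacement.  Inner fold of the sample at within-training position i is
    ``i mod inner`` (positions follow input order unless ``shuffle_inner``).
    """
    n_test = int(np.floor(n * test_fraction))
    if n_test < 1:
        raise ValueError("test fraction leaves no test samples")
    if n - n_test < inner:
        raise ValueError("outer training set smaller than inner fold count")
    rng = np.random.default_rng(seed)
    outer_splits, inner_splits = [], []
    for _ in range(outer):
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        outer_splits.append((train, test))
        order = rng.permutation(len(train)) if shuffle_inner else np.arange(len(train))
        fold_of = np.empty(len(train), dtype=int)
        fold_of[order] = np.arange(len(train)) % inner
        folds = []
        for f in range(inner):
            mask = fold_of == f
            folds.append((train[~mask], train[mask]))
        inner_splits.append(tuple(folds))
    return SplitPlan(outer=tuple(outer_splits), inner=tuple(inner_splits),
                     seed=seed)


# ---------------------------------------------------------------------------
# metrics


def enrichment_factor(labels, scores, top_fraction: float = 0.01) -> float:
    """Active rate in the top-scored fraction relative to the overall rate."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n = len(labels)
    k = max(1, int(np.floor(top_fraction * n)))
    order = np.argsort(-scores, kind="stable")
    top_rate = labels[order[:k]].mean()
    overall = labels.mean()
    if overall == 0:
        raise ValueError("no actives: enrichment factor undefined")
    return float(top_rate / overall)


def bedroc(labels, scores, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon & Bayly).

    Exponentially weights early recognition; 1 for a perfect ranking, ~0
    for a fully reversed one at typical alpha and low active fraction.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    N = len(labels)
    n = int(labels.sum())
    if n == 0 or n == N:
        raise ValueError("BEDROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    ranks = np.flatnonzero(labels[order] == 1) + 1  # 1-based ranks of actives
    ra = n / N
    s = np.sum(np.exp(-alpha * ranks / N))
    rie = (s / n) / ((1.0 / N) * (1.0 - np.exp(-alpha)) / (np.exp(alpha / N) - 1.0))
    factor = ra * np.sinh(alpha / 2.0) / (
        np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * ra)
    )
    const = 1.0 / (1.0 - np.exp(alpha * (1.0 - ra)))
    return float(rie * factor + const)


def compute_metrics(
    task: str, truth, predictions, *,
    threshold: float = 0.5, ef_fraction: float = 0.01,
    bedroc_alpha: float = 20.0,
) -> dict[str, float]:
    """The full metric set for one evaluation split.

    Regression ``predictions`` are point predictions; classification
    ``predictions`` are positive-class scores, dichotomized at
    ``threshold`` for the thresholded metrics.
    """
    truth = np.asarray(truth)
    pred = np.asarray(predictions, dtype=float)
    if len(truth) != len(pred):
        raise ValueError("truth and predictions differ in length")
    if task == "regression":
        rng_t = truth.max() - truth.min()
        if rng_t == 0:
            raise ValueError("zero truth range: %-normalized metrics undefined")
        sse = float(np.sum((truth - pred) ** 2))
        sst = float(np.sum((truth - truth.mean()) ** 2))
        return {
            "r2": 1.0 - sse / sst,
            "pct_mae": float(np.mean(np.abs(truth - pred))) / rng_t * 100.0,
            "pct_rmse": float(np.sqrt(np.mean((truth - pred) ** 2))) / rng_t * 100.0,
        }
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes required for classification metrics")
    p = np.clip(pred, 1e-15, 1 - 1e-15)
    calls = (pred >= threshold).astype(int)
    tp = int(np.sum((calls == 1) & (truth == 1)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return {
        "log_loss": float(log_loss(truth, p, labels=[0, 1])),
        "mcc": float(matthews_corrcoef(truth, calls)),
        "f1": float(f1_score(truth, calls, zero_division=0)),
        "balanced_accuracy": 0.5 * (sens + spec),
        "ef": enrichment_factor(truth, pred, ef_fraction),
        "bedroc": bedroc(truth, pred, bedroc_alpha),
    }


# ---------------------------------------------------------------------------
# rank-sum selection


@dataclass
class SelectionResult:
    top_model: str
    scores: pd.Series
    competitive: list[str]
    p_values: pd.DataFrame
    adjusted_p: pd.DataFrame
    tie_broken: bool = False


def rank_and_select(
    fold_metrics: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> SelectionResult:
    """Rank-sum scoring over fold-mean metrics plus Mann–Whitney/BH
    competitive-model identification.

    ``fold_metrics`` maps model id -> DataFrame (folds x metrics).  Ranks
    are per metric over fold means (best = rank 1); the top model minimizes
    the rank sum (ties broken by model id, logged).  A model is competitive
    if no metric differs from the top model at BH-adjusted p < alpha.
    """
    ids = sorted(fold_metrics)
    if len(ids) < 2:
        raise ValueError("need >= 2 models to rank")
    metrics = list(fold_metrics[ids[0]].columns)
    means = pd.DataFrame(
        {mid: fold_metrics[mid].mean() for mid in ids}
    ).T  # models x metrics
    ranks = pd.DataFrame(index=ids, columns=metrics, dtype=float)
    for m in metrics:
        vals = means[m].to_numpy(dtype=float)
        oriented = -vals if METRIC_ORIENTATION.get(m, True) else vals
        ranks[m] = rankdata(oriented)
    scores = ranks.sum(axis=1)
    best = scores.min()
    tied = sorted(scores[scores == best].index)
    top = tied[0]
    tie_broken = len(tied) > 1
    if tie_broken:
        logger.info("rank-sum tie among %s; selected %r by id", tied, top)

    pvals = pd.DataFrame(index=[i for i in ids if i != top], columns=metrics,
                         dtype=float)
    for mid in pvals.index:
        for m in metrics:
            a = fold_metrics[top][m].to_numpy(dtype=float)
            b = fold_metrics[mid][m].to_numpy(dtype=float)
            if np.array_equal(a, b):
                pvals.loc[mid, m] = 1.0
                continue
            method = "exact" if (len(a) <= 10 and len(b) <= 10
                                 and len(np.unique(np.concatenate([a, b])))
                                 == len(a) + len(b)) else "auto"
            try:
                p = mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
            except ValueError:
                p = mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
            pvals.loc[mid, m] = p
    flat = pvals.to_numpy().ravel()
    adj = multipletests(flat, method="fdr_bh")[1].reshape(pvals.shape)
    adj = pd.DataFrame(adj, index=pvals.index, columns=metrics)
    competitive = [top] + [mid for mid in pvals.index
                           if (adj.loc[mid] >= alpha).all()]
    return SelectionResult(top_model=top, scores=scores,
                           competitive=competitive, p_values=pvals,
                           adjusted_p=adj, tie_broken=tie_broken)


# ---------------------------------------------------------------------------
# nested evaluation


@dataclass(frozen=True)
class Candidate:
    """A model candidate for nested selection: id plus a seeded factory
    returning an object with fit/predict (and predict_proba for
    classification)."""

    id: str
    build: Callable[[int], object]


def _predict(est, X, task):
    if task == "classification":
        return est.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return est.predict(np.asarray(X, dtype=float))


@dataclass
class NestedReport:
    """Generalization estimate: per-metric mean and SE over outer splits,
    plus per-split details (selected model, metrics, test predictions)."""

    task: str
    per_split: list[dict]
    summary: pd.DataFrame

    @property
    def selected_ids(self) -> list[str]:
        return [d["selected"] for d in self.per_split]

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])


def run_nested_evaluation(
    candidates: Sequence[Candidate], X, y, task: str,
    plan: SplitPlan, seed: int = 0, metric_config: dict | None = None,
) -> NestedReport:
    """Inner-loop model selection + outer-loop generalization estimate.

    Per outer split: every candidate is fitted/evaluated over the inner
    folds, the rank-sum top model is selected, refitted on the outer
    training set, and scored on the untouched outer test set.
    """
    mc = metric_config or {}
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    per_split = []
    for s, (train, test) in enumerate(plan.outer):
        fold_metrics: dict[str, pd.DataFrame] = {}
        for cand in candidates:
            rows = []
            for f, (itrain, itest) in enumerate(plan.inner[s]):
                est = cand.build(seed + 1000 * s + f)
                est.fit(Xa[itrain], y[itrain])
                rows.append(compute_metrics(
                    task, y[itest], _predict(est, Xa[itest], task), **mc))
            fold_metrics[cand.id] = pd.DataFrame(rows)
        sel = rank_and_select(fold_metrics)
        top = next(c for c in candidates if c.id == sel.top_model)
        est = top.build(seed + 1000 * s)
        est.fit(Xa[train], y[train])
        pred = _predict(est, Xa[test], task)
        metrics = compute_metrics(task, y[test], pred, **mc)
        logger.info("outer split %d: selected %s (%s)", s, sel.top_model,
                    {k: round(v, 3) for k, v in metrics.items()})
        per_split.append({
            "split": s, "selected": sel.top_model, "metrics": metrics,
            "competitive": sel.competitive, "test_predictions": pred,
            "test_indices": test,
        })
    mdf = pd.DataFrame([d["metrics"] for d in per_split])
    summary = pd.DataFrame({
        "mean": mdf.mean(),
        "se": mdf.std(ddof=1) / np.sqrt(len(mdf)),
    })
    return NestedReport(task=task, per_split=per_split, summary=summary)


def adversarial_control(
    candidates: Sequence[Candidate], X, y, task: str,
    plan: SplitPlan, seed: int = 0, metric_config: dict | None = None,
) -> NestedReport:
    """Rerun the identical nested evaluation with responses permuted once
    (seeded): meaningful learning should collapse to chance."""
    rng = np.random.default_rng(seed)
    y_shuffled = rng.permutation(np.asarray(y))
    return run_nested_evaluation(candidates, X, y_shuffled, task, plan,
                                 seed=seed, metric_config=metric_config)
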