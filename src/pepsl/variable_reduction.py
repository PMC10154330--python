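"""Permutation-importance ranking and AIC-based variable subset selection.

The reduction runs in two stages:

1. a large random forest with out-of-bag (OOB) permutation importance ranks
   all variables; variables with negative importance are removed;
2. for each cumulative top-ranked subset a smaller forest is fitted and
   scored with AIC computed from OOB fit quality,

   * regression:      AIC = N ln(MSE) + 2k
   * classification:  AIC = 2 ln2 · N · H_p(q_theta) + 2k   (H_p in bits)

   where k is the number of variables in the subset.  The subset minimizing
   AIC is selected.

The forest uses balanced per-tree sampling for classification: every tree's
bootstrap draws the same number of samples (with replacement) from each
class, so rare classes are not swamped.  OOB votes and per-tree permutation
importance follow the randomForest/ranger convention: for each tree, each
variable is permuted among that tree's OOB rows and the decrease in OOB
accuracy (or increase in OOB MSE) is averaged over trees and normalized by
its standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

logger = logging.getLogger(__name__)


def aic_score(task: str, n: int, fit_quality: float, k: int) -> float:
    """AIC from fit quality: MSE (regression) or cross entropy in bits
    (classification)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if task == "regression":
        if fit_quality <= 0:
            raise ValueError("MSE must be > 0 for a finite regression AIC")
        return n * math.log(fit_quality) + 2 * k
    if task == "classification":
        if fit_quality < 0:
            raise ValueError("cross entropy must be >= 0")
        return 2.0 * math.log(2.0) * n * fit_quality + 2 * k
    raise ValueError(f"unknown task {task!r}")


class BalancedRandomForest:
    """Random forest over sklearn decision trees with OOB bookkeeping.

    Parameters
    ----------
    task : {"regression", "classification"}
    n_trees : number of trees.
    per_class_draw : "min", "mean" or int
        Classification only: per-class bootstrap draw size. "min" draws the
        minority-class count from every class; "mean" the mean class size.
    max_features : forwarded to the trees; defaults to sqrt(p) for
        classification and p/3 for regression.
    """

    def __init__(
        self,
        task: str,
        n_trees: int = 500,
        per_class_draw="min",
        max_features=None,
        seed: int | None = None,
    ):
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.task = task
        self.n_trees = n_trees
        self.per_class_draw = per_class_draw
        self.max_features = max_features
        self.seed = seed

    # -- fitting ----------------------------------------------------------

    def _draw_indices(self, rng, y):
        n = len(y)
        if self.task == "regression":
            return rng.integers(0, n, size=n)
        counts = np.bincount(y)
        if self.per_class_draw == "min":
            draw = int(counts[counts > 0].min())
        elif self.per_class_draw == "mean":
            draw = int(round(counts[counts > 0].mean()))
        else:
            draw = int(self.per_class_draw)
        idx = []
        for cls in np.flatnonzero(counts):
            members = np.flatnonzero(y == cls)
            idx.append(rng.choice(members, size=draw, replace=True))
        return np.concatenate(idx)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.task == "classification":
            classes = np.unique(y)
            if len(classes) < 2:
                raise ValueError("classification requires >= 2 classes")
            y = np.searchsorted(classes, y)
            self.classes_ = classes
            mf = self.max_features or max(1, int(math.sqrt(p)))
        else:
            y = y.astype(float)
            mf = self.max_features or max(1, p // 3)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.oob_masks_, self.inbag_counts_ = [], [], []
        # OOB aggregation
        if self.task == "classification":
            votes = np.zeros((n, len(self.classes_)))
        else:
            pred_sum = np.zeros(n)
            pred_cnt = np.zeros(n)
        for _ in range(self.n_trees):
            idx = self._draw_indices(rng, y)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if self.task == "classification":
                tree = DecisionTreeClassifier(
                    max_features=mf,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
            else:
                tree = DecisionTreeRegressor(
                    max_features=mf,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
            self.inbag_counts_.append(np.bincount(idx, minlength=n))
            if oob.any():
                pred = tree.predict(X[oob])
                if self.task == "classification":
                    votes[np.flatnonzero(oob), pred.astype(int)] += 1
                else:
                    pred_sum[oob] += pred
                    pred_cnt[oob] += 1
        self._X, self._y = X, y
        if self.task == "classification":
            total = votes.sum(axis=1)
            self.oob_vote_counts_ = votes
            with np.errstate(invalid="ignore"):
                self.oob_proba_ = np.where(
                    total[:, None] > 0, votes / np.maximum(total, 1)[:, None], np.nan
                )
        else:
            with np.errstate(invalid="ignore"):
                self.oob_prediction_ = np.where(
                    pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan
                )
        return self

    # -- OOB evaluation ---------------------------------------------------

    def oob_fit_quality(self) -> float:
        """OOB MSE (regression) or OOB cross entropy in bits
        (classification, binary), ignoring rows never out of bag."""
        if self.task == "regression":
            ok = ~np.isnan(self.oob_prediction_)
            return float(np.mean((self.oob_prediction_[ok] - self._y[ok]) ** 2))
        p1 = self.oob_proba_[:, 1] if self.oob_proba_.shape[1] > 1 else 1 - self.oob_proba_[:, 0]
        ok = ~np.isnan(p1)
        q = np.clip(p1[ok], 1e-12, 1 - 1e-12)
        yb = self._y[ok]
        return float(-np.mean(yb * np.log2(q) + (1 - yb) * np.log2(1 - q)))

    def oob_predictions(self):
        """Aggregated OOB predictions: vote proportions (classification,
        class called at 0.5) or mean tree predictions (regression)."""
        if self.task == "classification":
            return self.oob_proba_
        return self.oob_prediction_

    def oob_error(self) -> float:
        if self.task == "regression":
            return self.oob_fit_quality()
        p1 = self.oob_proba_[:, 1]
        ok = ~np.isnan(p1)
        calls = (p1[ok] >= 0.5).astype(int)
        return float(np.mean(calls != self._y[ok]))

    # -- permutation importance -------------------------------------------

    def permutation_importance(self, seed: int | None = None) -> pd.DataFrame:
        """Per-tree OOB permutation importance, normalized by standard error.

        Returns a DataFrame indexed like the feature axis with columns
        ``mean`` (decrease in accuracy / increase in MSE), ``se`` and
        ``normalized`` (mean / se; 0 where se == 0).
        """
        X, y = self._X, self._y
        n, p = X.shape
        rng = np.random.default_rng(self.seed if seed is None else seed)
        decreases = np.zeros((self.n_trees, p))
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_masks_)):
            if not oob.any():
                continue
            Xo, yo = X[oob], y[oob]
            m = len(yo)
            base_pred = tree.predict(Xo)
            if self.task == "classification":
                base = np.mean(base_pred == yo)
            else:
                base = np.mean((base_pred - yo) ** 2)
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]  # -2 marks leaves
            for j in used:
                perm = rng.permutation(m)
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                pred = tree.predict(Xp)
                if self.task == "classification":
                    decreases[t, j] = base - np.mean(pred == yo)
                else:
                    decreases[t, j] = np.mean((pred - yo) ** 2) - base
        mean = decreases.mean(axis=0)
        se = decreases.std(axis=0, ddof=1) / math.sqrt(self.n_trees) if self.n_trees > 1 else np.zeros(p)
        normalized = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        return pd.DataFrame({"mean": mean, "se": se, "normalized": normalized})


def fit_balanced_rf(
    matrix, targets, n_trees: int = 1000, task: str | None = None, **kw
) -> BalancedRandomForest:
    """Convenience wrapper accepting a DescriptorMatrix or DataFrame."""
    X = matrix.values if hasattr(matrix, "spec") else matrix
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(targets)
    if task is None:
        task = "classification" if y.dtype.kind in "biu" and len(np.unique(y)) <= 10 else "regression"
    return BalancedRandomForest(task=task, n_trees=n_trees, **kw).fit(X, y)


def permutation_importance(model: BalancedRandomForest, feature_names=None, seed=None) -> pd.DataFrame:
    """ImportanceRanking for a fitted balanced forest."""
    imp = model.permutation_importance(seed=seed)
    if feature_names is not None:
        imp.index = list(feature_names)
    return imp


@dataclass
class ReductionResult:
    """Selected variable subset with the full ranking and AIC trace."""

    selected: list[str]
    ranking: pd.DataFrame
    trace: pd.DataFrame

    @property
    def best_aic(self) -> float:
        return float(self.trace["aic"].min())


def reduce_variables(
    matrix,
    targets,
    task: str,
    rank_trees: int = 100_000,
    subset_trees: int = 1000,
    stride: int = 1,
    per_class_draw="min",
    seed: int | None = None,
) -> ReductionResult:
    """Rank variables by permutation importance and pick the cumulative
    top-ranked subset with the lowest AIC.

    ``stride`` evaluates every stride-th cumulative prefix (always including
    the full positive-importance set) to keep large-p runs tractable.
    """
    df = matrix.values if hasattr(matrix, "spec") else matrix
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame(df)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables to reduce")
    y = np.asarray(targets)
    rng = np.random.default_rng(seed)

    forest = BalancedRandomForest(
        task=task, n_trees=rank_trees, per_class_draw=per_class_draw,
        seed=int(rng.integers(0, 2**31 - 1)),
    ).fit(df.to_numpy(dtype=float), y)
    ranking = forest.permutation_importance(seed=int(rng.integers(0, 2**31 - 1)))
    ranking.index = list(df.columns)
    ranking = ranking.sort_values(
        ["normalized", "mean"], ascending=False, kind="stable"
    )
    kept = ranking[ranking["mean"] >= 0]
    if kept.empty or (ranking["mean"] < 0).all():
        raise ValueError("all variables have negative permutation importance")

    names = list(kept.index)
    sizes = list(range(1, len(names) + 1, stride))
    if sizes[-1] != len(names):
        sizes.append(len(names))
    rows = []
    n = len(y)
    for k in sizes:
        sub = BalancedRandomForest(
            task=task, n_trees=subset_trees, per_class_draw=per_class_draw,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).fit(df[names[:k]].to_numpy(dtype=float), y)
        fq = sub.oob_fit_quality()
        rows.append({
            "k": k, "n": n, "fit_quality": fq,
            "aic": aic_score(task, n, max(fq, 1e-12), k),
        })
    trace = pd.DataFrame(rows)
    best_k = int(trace.loc[trace["aic"].idxmin(), "k"])
    logger.info("variable reduction: %d -> %d variables (AIC %.2f)",
                df.shape[1], best_k, trace["aic"].min())
    return ReductionResult(selected=names[:best_k], ranking=ranking, trace=trace)
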