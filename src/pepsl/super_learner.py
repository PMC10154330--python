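"""Super-learner (stacked) ensembles with iterative base-model filtering.

A zoo of base models produces a holdout-prediction matrix via tenfold
cross-validation (each row predicted by models never trained on it).  A
generalized-linear meta-learner with non-negative coefficients is fitted on
the holdout matrix, and re-fitted inside another tenfold cross-validation to
give an n-models x 10-folds coefficient matrix.  Base models whose
coefficient is zero in more than ``zero_tolerance_folds`` folds are removed,
the meta-learner is refitted on the survivors, and the procedure repeats
until a fixed point (or an empty set).  The final ensemble refits the
surviving base models on all data and combines them with the final
meta-learner weights; classification ensembles store a max-F1 decision
threshold.

The non-negativity constraint is what makes exact zero coefficients (and
hence the filtering rule) well defined: regression weights come from NNLS,
classification weights from a bound-constrained logistic fit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier, ExtraTreesRegressor,
    GradientBoostingClassifier, GradientBoostingRegressor,
    RandomForestClassifier, RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-10

FAMILIES = (
    "neural-network",
    "gradient-boosting",
    "extreme-gradient-boosting",
    "generalized-linear",
    "random-forest",
    "extremely-randomized-trees",
)
#: Families whose inputs are standardized with training-fold statistics.
SCALED_FAMILIES = {"neural-network", "generalized-linear"}


@dataclass(frozen=True)
class BaseModelSpec:
    id: str
    family: str
    params: tuple = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def build_estimator(spec: BaseModelSpec, task: str, seed: int = 0):
    """Instantiate the sklearn/xgboost estimator behind a spec; non-tree
    families are wrapped with a StandardScaler pipeline."""
    p = spec.param_dict
    reg = task == "regression"
    if spec.family == "neural-network":
        cls = MLPRegressor if reg else MLPClassifier
        est = cls(
            hidden_layer_sizes=p.get("hidden", (32,)),
            alpha=p.get("alpha", 1e-3),
            max_iter=p.get("max_iter", 400),
            random_state=seed,
        )
    elif spec.family == "gradient-boosting":
        cls = GradientBoostingRegressor if reg else GradientBoostingClassifier
        est = cls(
            n_estimators=p.get("n_estimators", 100),
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 3),
            random_state=seed,
        )
    elif spec.family == "extreme-gradient-boosting":
        import xgboost as xgb

        cls = xgb.XGBRegressor if reg else xgb.XGBClassifier
        est = cls(
            n_estimators=p.get("n_estimators", 100),
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 4),
            verbosity=0,
            random_state=seed,
            **({} if reg else {"eval_metric": "logloss"}),
        )
    elif spec.family == "generalized-linear":
        est = Ridge(alpha=p.get("alpha", 1.0)) if reg else LogisticRegression(
            C=p.get("C", 1.0), max_iter=2000
        )
    elif spec.family == "random-forest":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        est = cls(n_estimators=p.get("n_estimators", 300), random_state=seed,
                  n_jobs=1)
    elif spec.family == "extremely-randomized-trees":
        cls = ExtraTreesRegressor if reg else ExtraTreesClassifier
        est = cls(n_estimators=p.get("n_estimators", 300), random_state=seed,
                  n_jobs=1)
    else:  # pragma: no cover
        raise ValueError(spec.family)
    if spec.family in SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def default_zoo(task: str, seed: int = 0, n_grid: int = 3,
                tree_estimators: int = 200) -> list[BaseModelSpec]:
    """A desk-scale model zoo: seeded random hyperparameter grids for the
    tunable families plus one default GLM/DRF/XRT, mirroring the production
    layout at reduced size."""
    rng = np.random.default_rng(seed)
    zoo = [
        BaseModelSpec("glm", "generalized-linear"),
        BaseModelSpec("drf", "random-forest",
                      (("n_estimators", tree_estimators),)),
        BaseModelSpec("xrt", "extremely-randomized-trees",
                      (("n_estimators", tree_estimators),)),
    ]
    for i in range(n_grid):
        zoo.append(BaseModelSpec(
            f"gbm{i + 1}", "gradient-boosting",
            (("n_estimators", int(rng.integers(60, 200))),
             ("learning_rate", float(10 ** rng.uniform(-1.5, -0.5))),
             ("max_depth", int(rng.integers(2, 5)))),
        ))
        zoo.append(BaseModelSpec(
            f"xgb{i + 1}", "extreme-gradient-boosting",
            (("n_estimators", int(rng.integers(60, 200))),
             ("learning_rate", float(10 ** rng.uniform(-1.5, -0.5))),
             ("max_depth", int(rng.integers(2, 6)))),
        ))
        zoo.append(BaseModelSpec(
            f"nn{i + 1}", "neural-network",
            (("hidden", (int(rng.integers(8, 64)),)),
             ("alpha", float(10 ** rng.uniform(-4, -1)))),
        ))
    return zoo


@dataclass
class HoldoutMatrix:
    """Rows = samples, columns = base-model holdout predictions from
    tenfold CV; ``fold_of[i]`` is the CV fold that held out row i."""

    predictions: pd.DataFrame
    fold_of: np.ndarray
    task: str

    @property
    def model_ids(self) -> list[str]:
        return list(self.predictions.columns)

    def subset(self, ids: Sequence[str]) -> "HoldoutMatrix":
        return HoldoutMatrix(self.predictions[list(ids)], self.fold_of, self.task)


def _cv(task: str, folds: int, seed: int):
    if task == "classification":
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return KFold(n_splits=folds, shuffle=True, random_state=seed)


def make_holdout_predictions(
    zoo: Sequence[BaseModelSpec], X, y, task: str,
    folds: int = 10, seed: int = 0,
) -> HoldoutMatrix:
    """Tenfold-CV holdout predictions for every zoo member.

    Models that fail to train, or whose predictions are non-finite or
    explosively large (unstable neural networks), are dropped with a logged
    warning rather than silently imputed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    cv = _cv(task, folds, seed)
    fold_of = np.empty(n, dtype=int)
    splits = list(cv.split(X, y if task == "classification" else None))
    for f, (_, test) in enumerate(splits):
        fold_of[test] = f
    scale = max(1.0, float(np.max(np.abs(y)))) if task == "regression" else 1.0
    cols: dict[str, np.ndarray] = {}
    for spec in zoo:
        pred = np.empty(n)
        try:
            for f, (train, test) in enumerate(splits):
                est = build_estimator(spec, task, seed=seed + f)
                est.fit(X[train], y[train])
                if task == "classification":
                    pred[test] = est.predict_proba(X[test])[:, 1]
                else:
                    pred[test] = est.predict(X[test])
        except Exception as exc:  # noqa: BLE001 - model failure is data
            logger.warning("base model %s failed (%s); column dropped",
                           spec.id, exc)
            continue
        if not np.isfinite(pred).all() or np.max(np.abs(pred)) > 1e4 * scale:
            logger.warning("base model %s produced unstable predictions; "
                           "column dropped", spec.id)
            continue
        cols[spec.id] = pred
    if not cols:
        raise RuntimeError("every base model failed or was unstable")
    return HoldoutMatrix(
        predictions=pd.DataFrame(cols), fold_of=fold_of, task=task,
    )


# ---------------------------------------------------------------------------
# meta-learner


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _fit_nonneg_glm(H: np.ndarray, y: np.ndarray, task: str):
    """Non-negative GLM fit: identity link via NNLS (intercept free-signed
    through a +/-1 column pair), logit link via bounded L-BFGS-B."""
    n, m = H.shape
    if task == "regression":
        A = np.column_stack([H, np.ones(n), -np.ones(n)])
        w, _ = nnls(A, y.astype(float))
        return w[:m], float(w[m] - w[m + 1])

    def obj(theta):
        w, b = theta[:m], theta[m]
        z = H @ w + b
        p = np.clip(_sigmoid(z), 1e-12, 1 - 1e-12)
        loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        g = (p - y) / n
        return loss, np.concatenate([H.T @ g, [g.sum()]])

    x0 = np.concatenate([np.full(m, 1.0 / m), [0.0]])
    bounds = [(0.0, None)] * m + [(None, None)]
    res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    w = res.x[:m].copy()
    w[w < ZERO_TOL] = 0.0
    return w, float(res.x[m])


@dataclass
class MetaFit:
    """Fold-wise coefficient matrix plus the final all-rows fit."""

    coef_matrix: pd.DataFrame  # models x folds
    weights: pd.Series
    intercept: float
    task: str
    cv_predictions: np.ndarray  # meta-learner CV predictions on holdout rows

    def predict(self, H: pd.DataFrame) -> np.ndarray:
        z = H[self.weights.index].to_numpy() @ self.weights.to_numpy() + self.intercept
        return _sigmoid(z) if self.task == "classification" else z


def fit_meta_learner(holdout: HoldoutMatrix, y, folds: int = 10,
                     seed: int = 0) -> MetaFit:
    """Fit the non-negative GLM stacker; evaluate it with another tenfold CV
    on the holdout matrix to obtain the n x folds coefficient matrix."""
    H = holdout.predictions.to_numpy(dtype=float)
    y = np.asarray(y)
    n, m = H.shape
    if n < folds:
        raise ValueError("fewer rows than meta-learner CV folds")
    cv = _cv(holdout.task, folds, seed)
    coef = np.zeros((m, folds))
    cv_pred = np.empty(n)
    for f, (train, test) in enumerate(
        cv.split(H, y if holdout.task == "classification" else None)
    ):
        w, b = _fit_nonneg_glm(H[train], y[train], holdout.task)
        coef[:, f] = w
        z = H[test] @ w + b
        cv_pred[test] = _sigmoid(z) if holdout.task == "classification" else z
    w_final, b_final = _fit_nonneg_glm(H, y, holdout.task)
    ids = holdout.model_ids
    return MetaFit(
        coef_matrix=pd.DataFrame(coef, index=ids,
                                 columns=[f"fold{f}" for f in range(folds)]),
        weights=pd.Series(w_final, index=ids),
        intercept=b_final,
        task=holdout.task,
        cv_predictions=cv_pred,
    )


def filter_base_models(
    coeff_fn: Callable[[list[str]], pd.DataFrame],
    model_ids: Sequence[str],
    zero_tolerance_folds: int = 5,
    zero_tol: float = ZERO_TOL,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove base models with > ``zero_tolerance_folds`` zero
    coefficients across CV folds, refitting after each removal.

    ``coeff_fn(ids)`` must return the models x folds coefficient matrix of a
    meta-learner refitted on exactly those models.  Stops at a fixed point
    or when no models remain; returns (survivors, iteration log).
    """
    survivors = list(model_ids)
    log: list[dict] = []
    while survivors:
        coefs = coeff_fn(survivors)
        zero_counts = (coefs.abs() < zero_tol).sum(axis=1)
        removed = list(zero_counts[zero_counts > zero_tolerance_folds].index)
        log.append({
            "n_models": len(survivors),
            "zero_counts": zero_counts.to_dict(),
            "removed": removed,
        })
        if not removed:
            break
        survivors = [m for m in survivors if m not in removed]
    return survivors, log


def select_classification_threshold(scores, labels) -> float:
    """Decision threshold maximizing F1 over the unique score values
    (predict positive at score >= threshold); ties pick the lowest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to select a threshold")
    best_t, best_f1 = None, -1.0
    npos = labels.sum()
    for t in np.unique(scores):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(npos - tp)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:  # strict: ties keep the earlier (lowest) threshold
            best_t, best_f1 = float(t), f1
    return best_t


@dataclass
class EnsembleModel:
    """A fitted super learner: surviving base models refit on all data plus
    the final meta-learner weights (and, for classifiers, a threshold)."""

    specs: list[BaseModelSpec]
    estimators: list
    weights: pd.Series
    intercept: float
    task: str
    threshold: float | None = None
    feature_names: list[str] | None = None
    coef_matrix: pd.DataFrame | None = None
    filter_log: list = field(default_factory=list)

    def base_predictions(self, X) -> pd.DataFrame:
        X = self._coerce(X)
        cols = {}
        for spec, est in zip(self.specs, self.estimators):
            if self.task == "classification":
                cols[spec.id] = est.predict_proba(X)[:, 1]
            else:
                cols[spec.id] = est.predict(X)
        return pd.DataFrame(cols)

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_names is not None:
            X = X[self.feature_names]
        return np.asarray(X, dtype=float)

    def predict(self, X) -> np.ndarray:
        """Meta-learner applied to the base-model predictions: the linear
        combination for regression, the logistic probability for
        classification."""
        H = self.base_predictions(X)
        z = H[self.weights.index].to_numpy() @ self.weights.to_numpy() + self.intercept
        return _sigmoid(z) if self.task == "classification" else z

    def predict_proba(self, X) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is for classification ensembles")
        p1 = self.predict(X)
        return np.column_stack([1 - p1, p1])

    def predict_label(self, X) -> np.ndarray:
        t = 0.5 if self.threshold is None else self.threshold
        return (self.predict(X) >= t).astype(int)

    @property
    def survivor_count(self) -> int:
        return len(self.specs)

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "task": self.task,
            "threshold": self.threshold,
            "intercept": self.intercept,
            "weights": self.weights.to_dict(),
            "feature_names": self.feature_names,
            "specs": [
                {"id": s.id, "family": s.family, "params": list(map(list, s.params))}
                for s in self.specs
            ],
            "filter_log": self.filter_log,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(self.estimators, d / "base_models.joblib")

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        d = Path(directory)
        man = json.loads((d / "manifest.json").read_text())
        specs = [
            BaseModelSpec(s["id"], s["family"],
                          tuple(tuple(p) for p in s["params"]))
            for s in man["specs"]
        ]
        return cls(
            specs=specs,
            estimators=joblib.load(d / "base_models.joblib"),
            weights=pd.Series(man["weights"]),
            intercept=man["intercept"],
            task=man["task"],
            threshold=man["threshold"],
            feature_names=man["feature_names"],
            filter_log=man.get("filter_log", []),
        )


def fit_super_learner(
    zoo: Sequence[BaseModelSpec], X, y, task: str,
    homogeneous: str | None = None,
    folds: int = 10, seed: int = 0,
    zero_tolerance_folds: int = 5,
    holdout: HoldoutMatrix | None = None,
) -> EnsembleModel:
    """Full stacking pipeline: holdout predictions -> meta-learner ->
    iterative base-model filtering -> final refit on all data.

    A precomputed ``holdout`` matrix (from :func:`make_holdout_predictions`
    with the same zoo/data/seed) may be supplied to avoid refitting.
    """
    if homogeneous is not None:
        zoo = [s for s in zoo if s.family == homogeneous]
        if not zoo:
            raise ValueError(f"no zoo members of family {homogeneous!r}")
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if holdout is None:
        holdout = make_holdout_predictions(zoo, Xa, y, task, folds=folds,
                                           seed=seed)

    def coeff_fn(ids):
        return fit_meta_learner(holdout.subset(ids), y, folds=folds,
                                seed=seed).coef_matrix

    survivors, flog = filter_base_models(
        coeff_fn, holdout.model_ids, zero_tolerance_folds=zero_tolerance_folds
    )
    if not survivors:
        raise RuntimeError("iterative filtering removed every base model")
    meta = fit_meta_learner(holdout.subset(survivors), y, folds=folds, seed=seed)
    spec_by_id = {s.id: s for s in zoo}
    final_specs = [spec_by_id[i] for i in survivors]
    estimators = []
    for spec in final_specs:
        est = build_estimator(spec, task, seed=seed)
        est.fit(Xa, y)
        estimators.append(est)
    threshold = None
    if task == "classification":
        threshold = select_classification_threshold(meta.cv_predictions, y)
    logger.info("super learner: %d/%d base models survive filtering",
                len(survivors), len(zoo))
    return EnsembleModel(
        specs=final_specs, estimators=estimators,
        weights=meta.weights, intercept=meta.intercept, task=task,
        threshold=threshold, feature_names=feature_names,
        coef_matrix=meta.coef_matrix, filter_log=flog,
    )


class SuperLearnerEstimator:
    """sklearn-like facade over :func:`fit_super_learner` so a super learner
    can enter model-selection loops alongside plain base models."""

    def __init__(self, zoo, task, folds=10, seed=0, homogeneous=None):
        self.zoo, self.task = zoo, task
        self.folds, self.seed, self.homogeneous = folds, seed, homogeneous

    def fit(self, X, y):
        self.model_ = fit_super_learner(
            self.zoo, X, y, self.task, homogeneous=self.homogeneous,
            folds=self.folds, seed=self.seed,
        )
        return self

    def predict(self, X):
        if self.task == "classification":
            return self.model_.predict_label(X)
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)
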