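"""Kernel SHAP attributions with ranked summaries and waterfall data.

Model-agnostic Shapley value estimation by kernel-weighted local linear
regression over feature coalitions: for each explained sample, coalition
masks are drawn (or fully enumerated when feasible), missing features are
imputed by averaging the model over a background set, and the attribution
vector is solved from a weighted least-squares system constrained so that
``E[f(X)] + sum(phi) = f(x)`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import rankdata


@dataclass
class ShapExplanation:
    """Additive attributions: samples x variables, plus E[f(X)] and f(x)."""

    values: pd.DataFrame
    expected_value: float
    predictions: pd.Series
    data: pd.DataFrame

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)


def _coalitions(p: int, budget: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Coalition masks and kernel weights.

    Enumerates all 2^p - 2 non-trivial masks with exact Shapley kernel
    weights when the budget allows; otherwise enumerates complete subset
    sizes from the extremes inward and fills the remaining budget with
    random masks of the remaining sizes, weighted by the residual kernel
    mass (the standard kernel-SHAP sampling scheme).
    """
    total = 2 ** p - 2
    kernel = lambda s: (p - 1) / (comb(p, s) * s * (p - s))  # noqa: E731
    if total <= budget:
        masks = np.zeros((total, p), dtype=bool)
        w = np.empty(total)
        k = 0
        for s in range(1, p):
            ws = kernel(s)
            for subset in combinations(range(p), s):
                masks[k, list(subset)] = True
                w[k] = ws
                k += 1
        return masks, w
    # size-level kernel mass
    size_mass = {s: kernel(s) * comb(p, s) for s in range(1, p)}
    masks_list, weights = [], []
    remaining = budget
    done = set()
    # pair sizes (s, p-s) from the extremes inward
    for s in range(1, p // 2 + 1):
        sizes = {s, p - s}
        need = int(sum(comb(p, t) for t in sizes - done))
        if need > remaining:
            break
        for t in sorted(sizes - done):
            for subset in combinations(range(p), t):
                m = np.zeros(p, dtype=bool)
                m[list(subset)] = True
                masks_list.append(m)
                weights.append(kernel(t))
            done.add(t)
        remaining -= need
    left = [s for s in range(1, p) if s not in done]
    if left and remaining > 0:
        mass = np.array([size_mass[s] for s in left])
        probs = mass / mass.sum()
        sizes = rng.choice(left, size=remaining, p=probs)
        per_mask_weight = mass.sum() / remaining
        for s in sizes:
            m = np.zeros(p, dtype=bool)
            m[rng.choice(p, size=s, replace=False)] = True
            masks_list.append(m)
            weights.append(per_mask_weight)
    return np.array(masks_list), np.array(weights)


def _masked_values(predict_fn, x, background, masks, batch: int = 64):
    """v_k = mean over background rows of f(x on mask k, background off)."""
    nb, p = background.shape
    out = np.empty(len(masks))
    for start in range(0, len(masks), batch):
        chunk = masks[start:start + batch]
        synth = np.repeat(background[None, :, :], len(chunk), axis=0)
        for i, m in enumerate(chunk):
            synth[i, :, m] = x[m][:, None]
        preds = np.asarray(predict_fn(synth.reshape(-1, p)), dtype=float)
        out[start:start + len(chunk)] = preds.reshape(len(chunk), nb).mean(axis=1)
    return out


def _solve(masks, weights, v, e_fx, fx):
    """Weighted least squares with the additivity constraint enforced by
    eliminating the last variable."""
    p = masks.shape[1]
    Z = masks.astype(float)
    delta = fx - e_fx
    A = Z[:, :-1] - Z[:, -1:]
    t = v - e_fx - Z[:, -1] * delta
    sw = np.sqrt(weights)
    phi_head, *_ = np.linalg.lstsq(A * sw[:, None], t * sw, rcond=None)
    phi = np.empty(p)
    phi[:-1] = phi_head
    phi[-1] = delta - phi_head.sum()
    return phi


def kernel_shap(
    model, samples, background, *,
    background_size: int = 100, n_samplings: int = 1000,
    seed: int = 0,
) -> ShapExplanation:
    """Kernel SHAP attributions for each row of ``samples``.

    ``model`` is either a callable ``f(X) -> array`` or an object with a
    ``predict`` method (classification ensembles are explained on the
    probability scale).  ``background`` rows beyond ``background_size`` are
    subsampled with the given seed.
    """
    predict_fn = model if callable(model) else model.predict
    X = samples.to_numpy(dtype=float) if isinstance(samples, pd.DataFrame) else np.asarray(samples, dtype=float)
    names = list(samples.columns) if isinstance(samples, pd.DataFrame) else [f"x{j}" for j in range(X.shape[1])]
    index = list(samples.index) if isinstance(samples, pd.DataFrame) else list(range(len(X)))
    B = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) else np.asarray(background, dtype=float)
    if len(B) == 0:
        raise ValueError("background set is empty")
    rng = np.random.default_rng(seed)
    if len(B) > background_size:
        B = B[rng.choice(len(B), size=background_size, replace=False)]
    e_fx = float(np.mean(predict_fn(B)))
    fx = np.asarray(predict_fn(X), dtype=float)
    p = X.shape[1]
    if p < 2:
        phi_all = (fx - e_fx)[:, None]
    else:
        phi_all = np.empty((len(X), p))
        for i, x in enumerate(X):
            masks, w = _coalitions(p, n_samplings, rng)
            v = _masked_values(predict_fn, x, B, masks)
            phi_all[i] = _solve(masks, w, v, e_fx, fx[i])
    return ShapExplanation(
        values=pd.DataFrame(phi_all, index=index, columns=names),
        expected_value=e_fx,
        predictions=pd.Series(fx, index=index, name="f(x)"),
        data=pd.DataFrame(X, index=index, columns=names),
    )


def summarize_shap(explanation: ShapExplanation, top_k: int = 20) -> pd.DataFrame:
    """Variables ranked by max - min SHAP value over the explained samples,
    with within-variable percentile ranks of the raw variable values.

    Returns a DataFrame indexed by variable (top_k rows, ordered by range
    descending) with columns ``shap_range``, ``shap_max``, ``shap_min``,
    and ``percentile_ranks`` holding per-sample ranks in [0, 1] (ties
    averaged).
    """
    if explanation.values.empty:
        raise ValueError("empty explanation")
    phi = explanation.values
    rng_ = phi.max() - phi.min()
    order = rng_.sort_values(ascending=False).index[:top_k]
    pct = {
        var: rankdata(explanation.data[var]) / len(explanation.data)
        for var in order
    }
    return pd.DataFrame({
        "shap_range": rng_[order],
        "shap_max": phi.max()[order],
        "shap_min": phi.min()[order],
        "percentile_ranks": [pct[v] for v in order],
    }, index=order)


def waterfall(explanation: ShapExplanation, sample_id, top_k: int = 10) -> pd.DataFrame:
    """Per-sample signed contributions ordered by |phi| descending, with a
    running total from E[f(X)] ending at f(x); contributions beyond
    ``top_k`` are aggregated into an ``(other)`` row."""
    if sample_id not in explanation.values.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    phi = explanation.values.loc[sample_id]
    ordered = sorted(phi.index, key=lambda v: (-abs(phi[v]), v))
    head, tail = ordered[:top_k], ordered[top_k:]
    rows = [(v, float(phi[v])) for v in head]
    if tail:
        rows.append(("(other)", float(phi[tail].sum())))
    running = explanation.expected_value
    out = []
    for name, contrib in rows:
        running += contrib
        out.append({"variable": name, "phi": contrib, "running_total": running})
    return pd.DataFrame(out)
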