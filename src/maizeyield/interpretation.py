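"""Feature attribution: permutation importance and Shapley values.

Both methods treat the model as a black-box function over the flat 84-vector
of panel features (75 variable-by-stage dynamics plus 9 periodic variables).
Permutation importance is the mean increase in test RMSE when one feature
column is shuffled across records.  Shapley attributions are estimated by
sampling feature permutations against a background set, walking each
permutation from the background vector to the explained vector; marginal
contributions telescope, so the attributions of every record sum exactly to
its prediction minus the base value (local accuracy).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import N_DYNAMIC, N_STAGES, feature_columns
from . import network as _net


def network_predict_fn(params, config):
    """Wrap trained network parameters as a flat-matrix predictor.

    Returns f(X) for X of shape (n, 84) in canonical feature order, with
    features on the scale the model was trained on (i.e. normalized).
    """
    n_dyn = N_DYNAMIC * N_STAGES

    def predict_fn(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        dyn = X[:, :n_dyn].reshape(n, N_DYNAMIC, N_STAGES).transpose(0, 2, 1)
        per = np.repeat(X[:, n_dyn:][:, None, :], N_STAGES, axis=1)
        inputs = np.concatenate([dyn, per], axis=2)
        chunk = 4096
        return np.concatenate([
            _net.forward_batch(params, config, inputs[i:i + chunk])
            for i in range(0, n, chunk)
        ])

    return predict_fn


def _rmse(y, p):
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(p)) ** 2)))


def _feature_index(feature, names):
    if isinstance(feature, (int, np.integer)):
        return int(feature)
    if feature not in names:
        raise KeyError(f"unknown feature {feature!r}")
    return names.index(feature)


def permutation_importance(
    predict_fn, X, y, feature, n_repeats: int = 10, seed: int = 0,
    feature_names=None,
):
    """Mean and sd of the RMSE increase from shuffling one feature column.

    The shuffle breaks the feature's association with the target while
    preserving its marginal distribution; a feature the model ignores scores
    zero up to floating-point noise.
    """
    names = list(feature_names) if feature_names is not None else feature_columns()
    j = _feature_index(feature, names)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    baseline = _rmse(y, predict_fn(X))
    rng = np.random.default_rng(seed)
    increases = np.empty(n_repeats)
    for r in range(n_repeats):
        Xs = X.copy()
        Xs[:, j] = Xs[rng.permutation(len(X)), j]
        increases[r] = _rmse(y, predict_fn(Xs)) - baseline
    return float(increases.mean()), float(increases.std())


def importance_table(
    predict_fn, X, y, n_repeats: int = 10, seed: int = 0, feature_names=None,
) -> pd.DataFrame:
    """Permutation importance of every feature, with normalized shares.

    Shares are percentages of the summed importances after flooring negative
    raw values at zero; the raw means are reported unfloored.
    """
    names = list(feature_names) if feature_names is not None else feature_columns()
    X = np.asarray(X, dtype=float)
    means = np.empty(len(names))
    sds = np.empty(len(names))
    for j in range(len(names)):
        means[j], sds[j] = permutation_importance(
            predict_fn, X, y, j, n_repeats=n_repeats, seed=seed + j,
            feature_names=names,
        )
    floored = np.maximum(means, 0.0)
    total = floored.sum()
    share = 100.0 * floored / total if total > 0 else np.zeros_like(floored)
    return pd.DataFrame({
        "feature": names, "importance_mean": means, "importance_sd": sds,
        "share_pct": share,
    })


def shapley_attribution(
    predict_fn, X_explain, X_background, n_samples: int = 128, seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Sampling Shapley attributions against a background set.

    Each sample pairs a random feature permutation with a background row
    (rows are cycled so every background row is used equally often, which
    makes the base value and the local-accuracy identity exact).  Returns
    (attributions of shape (n_records, n_features), base_value) where
    base_value is the mean background prediction and, for every record,
    base + sum(attributions) equals the model prediction.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    if len(X_background) == 0:
        raise ValueError("background set must be nonempty")
    n_records, n_features = X_explain.shape
    n_bg = len(X_background)
    # round up so each background row appears equally often
    n_samples = int(np.ceil(n_samples / n_bg) * n_bg)
    if n_samples < n_features:
        warnings.warn(
            f"n_samples={n_samples} is small for {n_features} features; "
            "attributions will be noisy", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n_features) for _ in range(n_samples)])
    bg_rows = X_background[np.arange(n_samples) % n_bg]
    base_value = float(predict_fn(X_background).mean())

    attributions = np.zeros((n_records, n_features))
    for i in range(n_records):
        x = X_explain[i]
        # path matrix: for each sample, F+1 points from background to x
        paths = np.repeat(bg_rows[:, None, :], n_features + 1, axis=1)
        for s in range(n_samples):
            for k, j in enumerate(perms[s]):
                paths[s, k + 1:, j] = x[j]
        vals = predict_fn(paths.reshape(-1, n_features)).reshape(n_samples, n_features + 1)
        deltas = np.diff(vals, axis=1)          # (n_samples, n_features) in path order
        contrib = np.zeros(n_features)
        for s in range(n_samples):
            contrib[perms[s]] += deltas[s]
        attributions[i] = contrib / n_samples
    return attributions, base_value


def rank_features(table: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Top-k features by importance; stable sort, ties keep feature-id order."""
    ordered = table.sort_values(
        "importance_mean", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return ordered.head(top_k)
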