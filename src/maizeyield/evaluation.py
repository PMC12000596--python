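"""Temporal validation regimes, metrics, bias classes and ablation harnesses.

Splitting follows three regimes: held-out-year (test = one calendar year,
remaining years shuffled 80/20 into train/validation), forward and backward
expanding windows (train/validation drawn only from years strictly before or
strictly after the test year), and in-season prediction (held-out-year plus
masking of growth stages after a cutoff).  Test records never appear in
train or validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import linear_model as _sklin
from sklearn import metrics as _skm

from .config import NetworkConfig
from .panel import (FeaturePanel, NormalizationStats, N_DYNAMIC, N_STAGES,
                    PERIODIC_VARIABLES, normalize_panel)
from . import network

STRATEGIES = ("holdout_year", "forward", "backward", "in_season")

#: absolute error (t/ha) beyond which a county prediction counts as a
#: significant over-/under-estimation
BIAS_THRESHOLD_T_HA = 0.9


class ConstantActualsError(ValueError):
    """R^2 is undefined when all actual values are identical.

    Carries a partial :class:`EvalReport` (``.report``) with ``r2=nan`` so the
    remaining metrics are still available to the caller.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


@dataclass
class SplitSpec:
    """Declarative description of one validation regime."""

    strategy: str = "holdout_year"
    test_year: int = 2021
    val_fraction: float = 0.2
    in_season_stage: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; use one of {STRATEGIES}")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if not 1 <= self.in_season_stage <= N_STAGES:
            raise ValueError("in_season_stage must be in 1..5")


def make_split(
    panel: FeaturePanel, spec: SplitSpec
) -> tuple[FeaturePanel, FeaturePanel, FeaturePanel]:
    """Split a panel into (train, val, test) per the spec.

    The test set is exactly the records of `test_year`.  The candidate pool
    is every other year (holdout/in_season), only earlier years (forward) or
    only later years (backward); the pool is shuffled with the spec seed and
    split `1 - val_fraction` / `val_fraction`.
    """
    years = panel.years
    if spec.test_year not in years:
        raise ValueError(f"test year {spec.test_year} not present in panel")
    test_mask = years == spec.test_year
    if spec.strategy in ("holdout_year", "in_season"):
        pool_mask = ~test_mask
    elif spec.strategy == "forward":
        pool_mask = years < spec.test_year
    else:  # backward
        pool_mask = years > spec.test_year
    pool_idx = np.flatnonzero(pool_mask)
    if np.unique(years[pool_idx]).size < 1:
        raise ValueError(f"no {spec.strategy} training years for test year {spec.test_year}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(pool_idx)
    n_val = int(round(spec.val_fraction * len(order)))
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    if train_idx.size == 0:
        raise ValueError("empty training set after split")
    return panel.subset(train_idx), panel.subset(val_idx), panel.subset(np.flatnonzero(test_mask))


def truncate_to_stage(panel: FeaturePanel, stage: int, sentinel: float = 0.0) -> FeaturePanel:
    """Mask dynamic values at growth stages after `stage` with the sentinel.

    Intended for use on already-normalized panels, where 0 is the neutral
    fill value; the panel shape is unchanged so one architecture serves every
    in-season cutoff.  `stage=5` is the identity.
    """
    if not 1 <= stage <= N_STAGES:
        raise ValueError("stage must be in 1..5")
    out = panel.copy()
    out.dynamic[:, stage:, :] = sentinel
    return out


@dataclass
class EvalReport:
    """Metrics plus per-record signed errors and bias classes."""

    r2: float
    rmse: float
    mse: float
    mae: float
    errors: np.ndarray
    bias_classes: np.ndarray = field(default=None)
    bias_counts: dict = field(default=None)

    def __post_init__(self):
        if self.bias_classes is None:
            self.bias_classes, self.bias_counts = classify_bias(self.errors)


def compute_metrics(y_true, y_pred) -> EvalReport:
    """R^2, RMSE, MSE and MAE plus signed errors (predicted - actual).

    R^2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2); RMSE = sqrt(MSE);
    raises :class:`ConstantActualsError` when the actuals are constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("need equal-length 1-D arrays with at least 2 records")
    mse = float(_skm.mean_squared_error(y_true, y_pred))
    mae = float(_skm.mean_absolute_error(y_true, y_pred))
    errors = y_pred - y_true
    if np.ptp(y_true) == 0:
        partial = EvalReport(r2=float("nan"), rmse=float(np.sqrt(mse)), mse=mse,
                             mae=mae, errors=errors)
        raise ConstantActualsError(
            f"R^2 undefined for constant actuals (RMSE={np.sqrt(mse):.6g}, "
            f"MAE={mae:.6g})", report=partial,
        )
    r2 = float(_skm.r2_score(y_true, y_pred))
    return EvalReport(r2=r2, rmse=float(np.sqrt(mse)), mse=mse, mae=mae, errors=errors)


def classify_bias(errors, threshold: float = BIAS_THRESHOLD_T_HA):
    """Label signed errors as over/under/within at the +/- threshold.

    The boundary is read strictly: an error of exactly +/- threshold is
    'within'.
    """
    errors = np.asarray(errors, dtype=float)
    if not np.isfinite(errors).all():
        raise ValueError("errors must be finite")
    labels = np.where(errors > threshold, "over",
                      np.where(errors < -threshold, "under", "within"))
    counts = {k: int((labels == k).sum()) for k in ("over", "under", "within")}
    return labels, counts


# -- end-to-end harness --------------------------------------------------------


@dataclass
class RunResult:
    report: EvalReport
    params: dict
    config: NetworkConfig
    stats: NormalizationStats
    history: dict
    split: SplitSpec


def _drop_group_columns(config_groups: str | None):
    """Feature indices (into the flat 84-vector) of a named temporal group."""
    if config_groups is None:
        return np.empty(0, dtype=int)
    n_dyn = N_DYNAMIC * N_STAGES
    per_index = {v: n_dyn + i for i, v in enumerate(PERIODIC_VARIABLES)}
    if config_groups == "monthly":
        return np.arange(n_dyn)
    if config_groups == "yearly":
        return np.array([per_index[v] for v in ("lon_norm", "lat_norm", "DFC", "DCM")])
    if config_groups == "five_year":
        return np.array([per_index[v] for v in
                         ("texture_class", "clay_pct", "silt_pct", "sand_pct", "soc_pct")])
    raise ValueError(f"unknown feature group {config_groups!r}")


def _mask_features(panel: FeaturePanel, idx: np.ndarray) -> FeaturePanel:
    if idx.size == 0:
        return panel
    X = panel.feature_matrix()
    X[:, idx] = 0.0
    return FeaturePanel.from_feature_matrix(panel, X)


def fit_evaluate(
    panel: FeaturePanel,
    split: SplitSpec,
    config: NetworkConfig,
    drop_group: str | None = None,
) -> RunResult:
    """Split, normalize on the training subset, train, and score the test year.

    For the in-season regime, stages after `split.in_season_stage` are masked
    (post-normalization zero sentinel) in train, validation and test, and the
    model is retrained for that cutoff.  `drop_group` zeroes one temporal
    feature group everywhere (feature-group ablations).
    """
    train_p, val_p, test_p = make_split(panel, split)
    train_n, stats = normalize_panel(train_p)
    val_n, _ = normalize_panel(val_p, stats) if len(val_p) else (val_p, stats)
    test_n, _ = normalize_panel(test_p, stats)
    if split.strategy == "in_season" and split.in_season_stage < N_STAGES:
        train_n = truncate_to_stage(train_n, split.in_season_stage)
        val_n = truncate_to_stage(val_n, split.in_season_stage) if len(val_n) else val_n
        test_n = truncate_to_stage(test_n, split.in_season_stage)
    idx = _drop_group_columns(drop_group)
    train_n, val_n, test_n = (_mask_features(p, idx) if len(p) else p
                              for p in (train_n, val_n, test_n))
    params, history = network.train(train_n, val_n if len(val_n) else None, config)
    preds = network.predict(params, config, test_n)
    report = compute_metrics(test_p.yields, preds)
    return RunResult(report=report, params=params, config=config, stats=stats,
                     history=history, split=split)


# -- baseline adapters ----------------------------------------------------------


class _FlatModel:
    """Adapter base: flattens panels to (n, 84) matrices for sklearn-style models."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, train: FeaturePanel, val: FeaturePanel | None = None):
        self.estimator.fit(train.feature_matrix(), train.yields)
        return self

    def predict(self, panel: FeaturePanel) -> np.ndarray:
        return np.asarray(self.estimator.predict(panel.feature_matrix()), dtype=float)


def lasso_factory(seed: int = 0, alpha: float = 0.01):
    return _FlatModel(_sklin.Lasso(alpha=alpha, max_iter=10000, random_state=seed))


def lightgbm_factory(seed: int = 0, **kwargs):
    import lightgbm

    defaults = dict(n_estimators=300, learning_rate=0.05, num_leaves=31,
                    random_state=seed, verbose=-1, n_jobs=1)
    defaults.update(kwargs)
    return _FlatModel(lightgbm.LGBMRegressor(**defaults))


class NetworkModel:
    """Adapter giving the network the same fit/predict surface as baselines."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params = None

    def fit(self, train: FeaturePanel, val: FeaturePanel | None = None):
        self.params, self.history = network.train(train, val, self.config)
        return self

    def predict(self, panel: FeaturePanel) -> np.ndarray:
        return network.predict(self.params, self.config, panel)


def network_factory(seed: int = 0, config: NetworkConfig | None = None, **flags):
    cfg_kwargs = {**(config.__dict__ if config else {}), **flags, "seed": seed}
    if config:
        cfg_kwargs["conv_filters"] = tuple(config.conv_filters)
    return NetworkModel(NetworkConfig(**cfg_kwargs))


# -- benchmark and ablation runners ---------------------------------------------


def run_benchmark(
    panel: FeaturePanel,
    model_factories: dict,
    years,
    repeats: int = 3,
    base_seed: int = 0,
    val_fraction: float = 0.2,
) -> pd.DataFrame:
    """Held-out-year benchmark matrix: per (year, model) mean +/- sd of R^2/RMSE.

    Every model sees identical splits and seeds within a repeat.  A model
    failure is recorded as NaN rather than aborting the run.
    """
    if not model_factories:
        raise ValueError("need at least one model factory")
    rows = []
    for year in years:
        for rep in range(repeats):
            seed = base_seed + rep
            spec = SplitSpec(strategy="holdout_year", test_year=int(year),
                             val_fraction=val_fraction, seed=seed)
            train_p, val_p, test_p = make_split(panel, spec)
            train_n, stats = normalize_panel(train_p)
            val_n, _ = normalize_panel(val_p, stats) if len(val_p) else (val_p, stats)
            test_n, _ = normalize_panel(test_p, stats)
            for name, factory in model_factories.items():
                try:
                    model = factory(seed=seed)
                    model.fit(train_n, val_n if len(val_n) else None)
                    report = compute_metrics(test_p.yields, model.predict(test_n))
                    r2, rmse = report.r2, report.rmse
                except Exception as exc:  # failure is data, not fatal
                    r2 = rmse = float("nan")
                    print(f"[run_benchmark] {name} failed for {year}/rep{rep}: {exc}")
                rows.append({"year": int(year), "model": name, "repeat": rep,
                             "r2": r2, "rmse": rmse})
    raw = pd.DataFrame(rows)
    summary = (raw.groupby(["year", "model"])[["r2", "rmse"]]
               .agg(["mean", "std"]).reset_index())
    summary.columns = ["year", "model", "r2_mean", "r2_sd", "rmse_mean", "rmse_sd"]
    summary.attrs["raw"] = raw
    return summary


MODULE_VARIANTS = {
    "full": {},
    "no_cnn": {"no_cnn": True},
    "drop_one_gru_layer": {"drop_one_gru_layer": True},
    "no_attention": {"no_attention": True},
}

FEATURE_GROUP_VARIANTS = {
    "full": None,
    "drop_monthly": "monthly",
    "drop_yearly": "yearly",
    "drop_five_year": "five_year",
}


def run_ablations(
    panel: FeaturePanel,
    config: NetworkConfig,
    mode: str = "modules",
    test_year: int | None = None,
    repeats: int = 3,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Module or feature-group ablation table with identical splits per variant.

    `modules` trains the full model and its three reduced graphs; every
    variant of a repeat shares the same split and seed.  `feature_groups`
    trains the full graph with one temporal feature group zeroed at a time.
    """
    if mode not in ("modules", "feature_groups"):
        raise ValueError("mode must be 'modules' or 'feature_groups'")
    test_year = int(test_year if test_year is not None else panel.years.max())
    rows = []
    variants = MODULE_VARIANTS if mode == "modules" else FEATURE_GROUP_VARIANTS
    for rep in range(repeats):
        seed = base_seed + rep
        spec = SplitSpec(strategy="holdout_year", test_year=test_year, seed=seed)
        for name, variant in variants.items():
            if mode == "modules":
                cfg = NetworkConfig(**{**config.__dict__, **variant, "seed": seed,
                                       "conv_filters": tuple(config.conv_filters)})
                result = fit_evaluate(panel, spec, cfg)
            else:
                cfg = NetworkConfig(**{**config.__dict__, "seed": seed,
                                       "conv_filters": tuple(config.conv_filters)})
                result = fit_evaluate(panel, spec, cfg, drop_group=variant)
            rows.append({"variant": name, "repeat": rep,
                         "r2": result.report.r2, "rmse": result.report.rmse})
    raw = pd.DataFrame(rows)
    summary = (raw.groupby("variant", sort=False)[["r2", "rmse"]]
               .agg(["mean", "std", "median"]).reset_index())
    summary.columns = ["variant", "r2_mean", "r2_sd", "r2_median",
                       "rmse_mean", "rmse_sd", "rmse_median"]
    summary.attrs["raw"] = raw
    return summary
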