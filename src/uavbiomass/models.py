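"""Fresh-biomass regression models and their evaluation.

Two learners are supported, mirroring common practice in UAV biomass
studies: a random forest (500 trees, 3 candidate predictors per split)
and partial least squares regression with the latent-variable count chosen
by inner cross-validated RMSE. Models are evaluated by leave-group-out
cross-validation (LGOCV): repeated random 70/30 plot-level splits, with
R², MAE and RMSE averaged over repeats.

Note on R²: it is defined here as the **squared Pearson correlation**
between actual and predicted values — not 1 − SSE/SST. The two diverge for
biased predictions: the correlation form always lies in [0, 1] and is
invariant to affine transforms of the predictions. MAE and RMSE retain the
bias and scale information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, ShuffleSplit

__all__ = [
    "ModelSpec",
    "CVScheme",
    "Metrics",
    "FittedModel",
    "EvaluationReport",
    "ResidualSummary",
    "metrics",
    "fit",
    "lgocv",
    "importance",
    "residual_summary",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which learner to fit and with what tuning parameters."""

    algorithm: str = "rf"        # "rf" | "plsr"
    rf_ntree: int = 500
    rf_mtry: int = 3
    plsr_max_lv: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "plsr"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.rf_ntree < 1 or self.plsr_max_lv < 1:
            raise ValueError("rf_ntree and plsr_max_lv must be >= 1")
        if self.rf_mtry < 1:
            raise ValueError("rf_mtry must be >= 1")


@dataclass(frozen=True)
class CVScheme:
    """Repeated random train/test splitting at the plot level."""

    train_fraction: float = 0.70
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


class Metrics(NamedTuple):
    r2: float
    mae: float
    rmse: float


def metrics(actual, predicted) -> Metrics:
    """R² (squared Pearson correlation), MAE and RMSE, in kg/m².

    R² is NaN (flagged undefined) when either vector has zero variance;
    MAE and RMSE are always returned.
    """
    x = np.asarray(actual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("actual and predicted must be 1-d vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    resid = x - y
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return Metrics(float("nan"), mae, rmse)
    r = float(np.corrcoef(x, y)[0, 1])
    return Metrics(r * r, mae, rmse)


@dataclass
class FittedModel:
    """A trained model bound to its predictor columns."""

    spec: ModelSpec
    predictors: tuple[str, ...]
    estimator: object
    n_components: int | None = None  # chosen latent variables (PLSR only)

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in table.columns]
        if missing:
            raise KeyError(f"table lacks predictor column(s): {missing}")
        X = table[list(self.predictors)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("predictor matrix contains missing values; "
                             "drop or impute flagged plots explicitly first")
        return X

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        pred = np.asarray(self.estimator.predict(self._matrix(table)), dtype=float)
        return pred.reshape(-1)


def fit(
    spec: ModelSpec,
    train: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "fb_measured",
) -> FittedModel:
    """Fit the specified learner on a training table.

    Missing values raise — there is no silent imputation. For the random
    forest, mtry larger than the predictor count is clipped with a
    warning. PLSR standardizes predictors and selects the latent-variable
    count (1..plsr_max_lv) minimising 5-fold inner-CV RMSE.
    """
    predictors = tuple(predictors)
    if len(predictors) < 1:
        raise ValueError("need at least one predictor")
    if response not in train.columns:
        raise KeyError(f"response column {response!r} not in table")
    X = train[list(predictors)].to_numpy(dtype=float)
    y = train[response].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data contain missing values")

    if spec.algorithm == "rf":
        mtry = spec.rf_mtry
        if mtry > len(predictors):
            warnings.warn(
                f"rf_mtry={mtry} exceeds {len(predictors)} predictors; clipped"
            )
            mtry = len(predictors)
        est = RandomForestRegressor(
            n_estimators=spec.rf_ntree,
            max_features=mtry,
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        )
        est.fit(X, y)
        return FittedModel(spec=spec, predictors=predictors, estimator=est)

    # PLSR: inner 5-fold CV over the latent-variable count
    max_lv = min(spec.plsr_max_lv, len(predictors), len(train) - 1)
    n_splits = min(5, len(train))
    best_k, best_rmse = 1, np.inf
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    for k in range(1, max_lv + 1):
        sq_errs = []
        for tr, te in kf.split(X):
            m = PLSRegression(n_components=k, scale=True)
            m.fit(X[tr], y[tr])
            sq_errs.append(np.mean((y[te] - m.predict(X[te]).ravel()) ** 2))
        rmse = float(np.sqrt(np.mean(sq_errs)))
        if rmse < best_rmse - 1e-12:
            best_k, best_rmse = k, rmse
    est = PLSRegression(n_components=best_k, scale=True)
    est.fit(X, y)
    return FittedModel(spec=spec, predictors=predictors, estimator=est, n_components=best_k)


def importance(fitted: FittedModel, train: pd.DataFrame, response: str = "fb_measured") -> dict[str, float]:
    """Relative predictor importance on a 0–100 scale (max → 100).

    Random forest: permutation importance (mean increase in squared error
    when a predictor is shuffled, 5 seeded repeats). PLSR: absolute
    standardized regression coefficients. Only the maximum is pinned (to
    100); the minimum is not forced to 0, so ratios are preserved.
    """
    X = fitted._matrix(train)
    y = train[response].to_numpy(dtype=float)
    if fitted.spec.algorithm == "rf":
        res = permutation_importance(
            fitted.estimator, X, y, n_repeats=5,
            random_state=fitted.spec.seed, scoring="neg_mean_squared_error",
        )
        raw = np.clip(res.importances_mean, 0.0, None)
    else:
        coef = np.asarray(fitted.estimator.coef_, dtype=float).reshape(-1)
        raw = np.abs(coef) * X.std(axis=0, ddof=1)
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else np.full_like(raw, 100.0)
    return {name: float(v) for name, v in zip(fitted.predictors, scaled)}


@dataclass
class EvaluationReport:
    """LGOCV outcome: averaged metrics, per-repeat metrics, pooled
    predictions, and 0–100 predictor importance (from a fit on the full
    table)."""

    r2: float
    mae: float
    rmse: float
    residual_sd: float                  # mean over repeats of residual SD
    per_repeat: pd.DataFrame            # columns: repeat, r2, mae, rmse, residual_sd
    predictions: pd.DataFrame           # columns: repeat, row, actual, predicted
    importance: dict[str, float]
    pooled: Metrics                     # metrics on pooled predictions
    spec: ModelSpec = field(default_factory=ModelSpec)
    scheme: CVScheme = field(default_factory=CVScheme)

    @property
    def pooled_residuals(self) -> np.ndarray:
        return (self.predictions["actual"] - self.predictions["predicted"]).to_numpy()


def lgocv(
    spec: ModelSpec,
    table: pd.DataFrame,
    predictors: Sequence[str],
    scheme: CVScheme = CVScheme(),
    response: str = "fb_measured",
) -> EvaluationReport:
    """Leave-group-out cross-validation.

    Each repeat draws a fresh random split (train_fraction of plots for
    training, the rest held out), fits, predicts the held-out plots and
    scores them; the report averages metrics over repeats. A plot is never
    in both partitions of one repeat.
    """
    if len(table) < 10:
        raise ValueError(
            f"only {len(table)} plots; cross-validation below 10 plots is not meaningful"
        )
    predictors = tuple(predictors)
    table = table.reset_index(drop=True)
    splitter = ShuffleSplit(
        n_splits=scheme.repeats, train_size=scheme.train_fraction,
        random_state=scheme.seed,
    )
    rows, preds = [], []
    for rep, (tr, te) in enumerate(splitter.split(np.zeros(len(table))), start=1):
        model = fit(spec, table.iloc[tr], predictors, response=response)
        predicted = model.predict(table.iloc[te])
        actual = table.iloc[te][response].to_numpy(dtype=float)
        m = metrics(actual, predicted)
        resid_sd = float(np.std(actual - predicted, ddof=1))
        rows.append(dict(repeat=rep, r2=m.r2, mae=m.mae, rmse=m.rmse, residual_sd=resid_sd))
        preds.append(pd.DataFrame(dict(repeat=rep, row=te, actual=actual, predicted=predicted)))
    per_repeat = pd.DataFrame(rows)
    predictions = pd.concat(preds, ignore_index=True)
    full_model = fit(spec, table, predictors, response=response)
    pooled = metrics(predictions["actual"], predictions["predicted"])
    return EvaluationReport(
        r2=float(per_repeat["r2"].mean()),
        mae=float(per_repeat["mae"].mean()),
        rmse=float(per_repeat["rmse"].mean()),
        residual_sd=float(per_repeat["residual_sd"].mean()),
        per_repeat=per_repeat,
        predictions=predictions,
        importance=importance(full_model, table, response=response),
        pooled=pooled,
        spec=spec,
        scheme=scheme,
    )


class ResidualSummary(NamedTuple):
    sd: float
    ci_lo: float
    ci_hi: float


def residual_summary(report: EvaluationReport, seed: int = 0, n_boot: int = 2000) -> ResidualSummary:
    """SD of the pooled (actual − predicted) residuals with a seeded
    percentile-bootstrap 95% interval."""
    resid = report.pooled_residuals
    if resid.size == 0:
        raise ValueError("report has no pooled predictions")
    sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, resid.size, size=(n_boot, resid.size))
    boot = np.std(resid[idx], axis=1, ddof=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ResidualSummary(sd=sd, ci_lo=float(lo), ci_hi=float(hi))
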