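"""Temporal screening of genotype panels across environments.

A calibrated biomass model is applied to early/late maturity panels grown
under drought simulation and control conditions, at several thermal-time
points. Trials are labelled ED/LD (early/late, drought) and EC/LC
(early/late, control). Per trial × GDD × year the predicted-biomass
distribution is summarised as a boxplot (median, quartiles, IQR-rule
outliers, seeded percentile-bootstrap 95% CI of the median), and
control − drought median contrasts quantify the drought effect.

Quartiles use the linear-interpolation convention (numpy default); the
outlier flags depend on it, so it is fixed here rather than configurable.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .models import FittedModel

__all__ = [
    "trial_label",
    "predict_screening",
    "group_summary",
    "drought_contrast",
    "bin_gdd",
]

logger = logging.getLogger(__name__)

_LABELS = {
    ("early", "drought"): "ED",
    ("late", "drought"): "LD",
    ("early", "control"): "EC",
    ("late", "control"): "LC",
}


def trial_label(maturity: str, environment: str) -> str:
    """Map (maturity, environment) to the trial code ED/LD/EC/LC."""
    try:
        return _LABELS[(maturity, environment)]
    except KeyError:
        raise ValueError(f"no trial label for {(maturity, environment)!r}") from None


def bin_gdd(values, nominal: Sequence[float] = (230, 390, 706, 917), width: float = 25.0):
    """Snap observed GDDs to the nearest nominal screening time point.

    Flights across years land within a window of the planned thermal time;
    alignment uses nominal bins of half-width ``width`` (°C·days). Values
    outside every bin raise.
    """
    values = np.asarray(values, dtype=float)
    nominal = np.asarray(nominal, dtype=float)
    idx = np.abs(values[:, None] - nominal[None, :]).argmin(axis=1)
    snapped = nominal[idx]
    off = np.abs(values - snapped) > width
    if np.any(off):
        raise ValueError(
            f"GDD values {values[off]} fall outside every nominal bin ±{width}"
        )
    return snapped


def predict_screening(model: FittedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predict FB for every screening plot.

    Adds ``fb_pred`` (negative raw predictions clamped to 0, count logged)
    and, when maturity/environment columns are present, the ``trial``
    label. Raises KeyError naming any missing predictor column.
    """
    out = table.copy()
    if len(table) == 0:
        out["fb_pred"] = np.zeros(0)
        return out
    raw = model.predict(table)
    n_neg = int(np.sum(raw < 0))
    if n_neg:
        logger.info("clamped %d negative biomass predictions to 0", n_neg)
    out["fb_pred"] = np.clip(raw, 0.0, None)
    if {"maturity", "environment"}.issubset(out.columns):
        out["trial"] = [
            trial_label(m, e) for m, e in zip(out["maturity"], out["environment"])
        ]
    return out


def _boxplot_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return dict(median=float(med), q1=float(q1), q3=float(q3),
                outliers=outliers.tolist(), n_outliers=int(outliers.size))


def _median_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    med = np.median(values[idx], axis=1)
    lo, hi = np.percentile(med, [2.5, 97.5])
    return float(lo), float(hi)


def group_summary(
    results: pd.DataFrame,
    value: str = "fb_pred",
    by: Sequence[str] = ("trial", "gdd", "year"),
    seed: int = 0,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Boxplot statistics per group: median, Q1/Q3, IQR-rule outliers and
    a seeded percentile-bootstrap 95% CI of the median."""
    by = list(by)
    rng = np.random.default_rng(seed)
    rows = []
    for keys, grp in results.groupby(by, sort=True):
        values = grp[value].to_numpy(dtype=float)
        stats = _boxplot_stats(values)
        ci_lo, ci_hi = _median_ci(values, rng, n_boot)
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row.update(n=values.size, **stats, ci_lo=ci_lo, ci_hi=ci_hi)
        rows.append(row)
    return pd.DataFrame(rows)


def drought_contrast(
    results: pd.DataFrame,
    value: str = "fb_pred",
    by: Sequence[str] = ("maturity", "gdd", "year"),
    seed: int = 0,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Control − drought median difference per stratum with a seeded
    bootstrap 95% CI; ``excludes_zero`` flags strata where the interval
    does not cover 0. Strata missing one arm are skipped with a warning.
    """
    if "environment" not in results.columns:
        raise KeyError("results must carry an 'environment' column")
    by = list(by)
    rng = np.random.default_rng(seed)
    rows = []
    for keys, grp in results.groupby(by, sort=True):
        arms = {env: g[value].to_numpy(dtype=float) for env, g in grp.groupby("environment")}
        if "control" not in arms or "drought" not in arms:
            warnings.warn(f"stratum {keys} has a single arm; skipped")
            continue
        c, d = arms["control"], arms["drought"]
        diff = float(np.median(c) - np.median(d))
        ci = np.median(c[rng.integers(0, c.size, size=(n_boot, c.size))], axis=1) - \
            np.median(d[rng.integers(0, d.size, size=(n_boot, d.size))], axis=1)
        lo, hi = np.percentile(ci, [2.5, 97.5])
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row.update(
            n_control=c.size, n_drought=d.size,
            control_median=float(np.median(c)), drought_median=float(np.median(d)),
            diff=diff, ci_lo=float(lo), ci_hi=float(hi),
            excludes_zero=bool(lo > 0 or hi < 0),
        )
        rows.append(row)
    return pd.DataFrame(rows)
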