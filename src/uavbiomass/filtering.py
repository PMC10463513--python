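"""Correlation-based predictor pruning.

A panel of vegetation indices computed from five shared bands is heavily
collinear. Before regression the panel is reduced by pairwise-correlation
elimination: among every pair with |r| above a cutoff (0.8 by default),
the member with the larger mean absolute correlation (MAC) against the
surviving variables is removed, and the bookkeeping is repeated until no
pair exceeds the cutoff. Canopy cover and plant height are kept
unconditionally; only the index panel is filtered.

Two traversal variants are provided:

* ``exact`` (default) — repeatedly take the currently largest |r| pair
  among survivors and recompute MACs after every removal; deterministic
  and order-independent.
* ``greedy`` — one pass over pairs in decreasing |r| with MACs computed
  once on the full set; faster, order-dependent, kept for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "RemovalStep",
    "correlation_report",
    "mac_filter",
    "select_predictors",
    "plot_correlation",
]

#: MAC differences below this are ties, broken by registry (column) order.
MAC_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations with two-sided p-values."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        rv = self.r.to_numpy()
        if not np.allclose(rv, rv.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(rv), 1.0):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(rv) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")

    @property
    def n_pairs(self) -> int:
        """Number of unique unordered variable pairs, k·(k−1)/2."""
        k = len(self.variables)
        return k * (k - 1) // 2

    def pairs(self) -> list[tuple[str, str, float, float]]:
        """All unique pairs as (a, b, r, p), in variable order."""
        out = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                out.append((a, b, float(self.r.loc[a, b]), float(self.p.loc[a, b])))
        return out


def correlation_report(table: pd.DataFrame, columns: Sequence[str] | None = None) -> CorrelationReport:
    """Pearson correlation matrix over the given numeric columns.

    p-values come from the two-sided t test with n−2 degrees of freedom.
    Zero-variance columns are excluded with a warning; rows with any
    missing value in the selected columns are dropped listwise.
    """
    columns = list(columns) if columns is not None else list(table.columns)
    data = table[columns].astype(float).dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for a correlation report")
    keep = []
    for c in columns:
        if np.std(data[c].to_numpy()) == 0.0:
            warnings.warn(f"column {c!r} has zero variance; excluded from the report")
        else:
            keep.append(c)
    values = data[keep].to_numpy()
    n = values.shape[0]
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return CorrelationReport(
        variables=tuple(keep),
        r=pd.DataFrame(r, index=keep, columns=keep),
        p=pd.DataFrame(p, index=keep, columns=keep),
        n=n,
    )


@dataclass(frozen=True)
class RemovalStep:
    """One elimination: the offending pair, both MACs, and the loser."""

    pair: tuple[str, str]
    r: float
    mac: dict[str, float] = field(default_factory=dict)
    removed: str = ""
    tie_broken: bool = False


def _mac(r: pd.DataFrame, var: str, survivors: list[str]) -> float:
    others = [v for v in survivors if v != var]
    return float(np.mean([abs(r.loc[var, o]) for o in others])) if others else 0.0


def mac_filter(
    report: CorrelationReport,
    cutoff: float = 0.8,
    protected: Iterable[str] = (),
    method: str = "exact",
) -> tuple[list[str], list[RemovalStep]]:
    """Eliminate variables until no surviving pair has |r| > cutoff.

    Within each offending pair the variable with the larger mean absolute
    correlation against the current survivors is removed (MAC ties broken
    by removing the variable later in column order). ``protected`` names
    are never removed. Returns (survivors in original order, removal log).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    protected = set(protected)
    unknown = protected - set(report.variables)
    if unknown:
        raise KeyError(f"protected names not in report: {sorted(unknown)}")
    if method not in ("exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    survivors = list(report.variables)
    order = {v: i for i, v in enumerate(report.variables)}
    r = report.r
    log: list[RemovalStep] = []

    if method == "greedy":
        full_mac = {v: _mac(r, v, survivors) for v in survivors}
        candidates = sorted(
            report.pairs(), key=lambda t: (-abs(t[2]), order[t[0]], order[t[1]])
        )
        for a, b, rv, _ in candidates:
            if abs(rv) <= cutoff or a not in survivors or b not in survivors:
                continue
            removed = _loser(a, b, full_mac[a], full_mac[b], order, protected)
            if removed is None:
                continue
            survivors.remove(removed)
            log.append(RemovalStep(pair=(a, b), r=rv, mac={a: full_mac[a], b: full_mac[b]},
                                   removed=removed,
                                   tie_broken=abs(full_mac[a] - full_mac[b]) <= MAC_TIE_TOL))
        return survivors, log

    while True:
        best = None
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                if a in protected and b in protected:
                    continue
                rv = abs(float(r.loc[a, b]))
                if rv > cutoff and (best is None or rv > best[0]):
                    best = (rv, a, b)
        if best is None:
            break
        _, a, b = best
        mac_a, mac_b = _mac(r, a, survivors), _mac(r, b, survivors)
        removed = _loser(a, b, mac_a, mac_b, order, protected)
        assert removed is not None  # pair with both protected was skipped above
        survivors.remove(removed)
        log.append(RemovalStep(pair=(a, b), r=float(r.loc[a, b]),
                               mac={a: mac_a, b: mac_b}, removed=removed,
                               tie_broken=abs(mac_a - mac_b) <= MAC_TIE_TOL))

    # certified post-condition: no surviving pair above the cutoff
    # (protected pairs are exempt — they are kept by decree, not by r)
    for i, a in enumerate(survivors):
        for b in survivors[i + 1:]:
            if a in protected and b in protected:
                continue
            assert abs(float(r.loc[a, b])) <= cutoff, (a, b)
    return survivors, log


def _loser(a, b, mac_a, mac_b, order, protected):
    if a in protected and b in protected:
        return None
    if a in protected:
        return b
    if b in protected:
        return a
    if abs(mac_a - mac_b) <= MAC_TIE_TOL:
        return a if order[a] > order[b] else b  # tie: drop the later column
    return a if mac_a > mac_b else b


class SelectionResult(NamedTuple):
    table: pd.DataFrame
    retained: list[str]          # always_keep + surviving VI names
    log: list[RemovalStep]


def select_predictors(
    table: pd.DataFrame,
    vi_names: Sequence[str],
    always_keep: Sequence[str] = ("CC", "PH"),
    cutoff: float = 0.8,
    method: str = "exact",
) -> SelectionResult:
    """Reduce the modelling table: keep CC/PH unconditionally, filter the
    VI panel by MAC elimination, drop the eliminated VI columns."""
    missing = [c for c in list(always_keep) + list(vi_names) if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    if len(vi_names) == 0:
        return SelectionResult(table.copy(), list(always_keep), [])
    report = correlation_report(table, list(vi_names))
    survivors, log = mac_filter(report, cutoff=cutoff, method=method)
    retained = list(always_keep) + survivors
    dropped = [v for v in vi_names if v not in survivors]
    return SelectionResult(table.drop(columns=dropped), retained, log)


def plot_correlation(report: CorrelationReport, path, alpha: float = 0.05) -> None:
    """Save a correlation heatmap; non-significant cells (p ≥ alpha) are
    marked with a cross."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(report.variables)
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * k), max(5, 0.35 * k)))
    im = ax.imshow(report.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), report.variables, rotation=90, fontsize=7)
    ax.set_yticks(range(k), report.variables, fontsize=7)
    for i in range(k):
        for j in range(k):
            if i != j and report.p.iloc[i, j] >= alpha:
                ax.text(j, i, "×", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
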