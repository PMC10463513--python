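"""Correlation reporting and mean-absolute-correlation elimination,
including an independent step-by-step oracle of the published rule."""

import numpy as np
import pandas as pd
import pytest

from uavbiomass.filtering import (
    CorrelationReport,
    correlation_report,
    mac_filter,
    select_predictors,
)
from uavbiomass.synthetic import make_collinear_panel


def report_from_r(r: np.ndarray, names, n: int = 50) -> CorrelationReport:
    """Build a report straight from a correlation matrix (p set to 0)."""
    rdf = pd.DataFrame(r, index=list(names), columns=list(names))
    p = pd.DataFrame(np.zeros_like(r), index=list(names), columns=list(names))
    return CorrelationReport(variables=tuple(names), r=rdf, p=p, n=n)


def reference_elimination(r: pd.DataFrame, cutoff: float) -> list[str]:
    """Naive exhaustive re-trace of the elimination rule: repeatedly take
    the largest surviving |r| pair, compute each member's mean absolute
    correlation over the current survivors, drop the larger (ties: the
    later column), until no pair exceeds the cutoff."""
    surv = list(r.columns)
    while True:
        sub = r.loc[surv, surv].abs().to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= cutoff:
            return surv
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = min(i, j), max(i, j)
        mac_i = sub[i].sum() / (len(surv) - 1)
        mac_j = sub[j].sum() / (len(surv) - 1)
        if abs(mac_i - mac_j) <= 1e-12:
            drop = j
        else:
            drop = i if mac_i > mac_j else j
        surv.pop(drop)


class TestCorrelationReport:
    def test_pair_count_31_variables(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(40, 31)),
                             columns=[f"VI{i:02d}" for i in range(31)])
        report = correlation_report(table)
        assert report.n_pairs == 465
        assert len(report.pairs()) == 465

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"x": rng.normal(size=20)})
        table["y"] = table["x"]
        report = correlation_report(table)
        assert report.r.loc["x", "y"] == pytest.approx(1.0)

    def test_affine_dependence(self):
        x = np.arange(30.0)
        report = correlation_report(pd.DataFrame({"x": x, "y": 2 * x + 3}))
        assert report.r.loc["x", "y"] == pytest.approx(1.0)
        assert report.p.loc["x", "y"] < 1e-12

    def test_p_values_match_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        report = correlation_report(table)
        for a, b, r, p in report.pairs():
            expected = stats.pearsonr(table[a], table[b])
            assert r == pytest.approx(expected.statistic)
            assert p == pytest.approx(expected.pvalue, rel=1e-6)

    def test_zero_variance_column_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.normal(size=20), "flat": np.ones(20)})
        table["y"] = rng.normal(size=20)
        with pytest.warns(UserWarning, match="flat"):
            report = correlation_report(table)
        assert "flat" not in report.variables

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            correlation_report(pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}))


class TestMacFilter:
    def test_hand_traced_triangle(self):
        """|r|: A–B 0.9, A–C 0.85, B–C 0.1 at cutoff 0.8 → A has the
        largest MAC (0.875 vs 0.5) and is removed; B–C is below the
        cutoff, so {B, C} survive after one step."""
        r = np.array([[1.0, 0.9, 0.85], [0.9, 1.0, 0.1], [0.85, 0.1, 1.0]])
        survivors, log = mac_filter(report_from_r(r, "ABC"), cutoff=0.8)
        assert survivors == ["B", "C"]
        assert len(log) == 1
        assert log[0].removed == "A"
        assert log[0].mac["A"] == pytest.approx(0.875)
        assert log[0].mac["B"] == pytest.approx(0.5)

    def test_no_pair_above_cutoff(self):
        r = np.eye(4) * 0.5 + 0.5 * np.eye(4)  # identity
        survivors, log = mac_filter(report_from_r(np.eye(4), "ABCD"), cutoff=0.8)
        assert survivors == ["A", "B", "C", "D"]
        assert log == []

    def test_cutoff_domain(self):
        with pytest.raises(ValueError):
            mac_filter(report_from_r(np.eye(3), "ABC"), cutoff=1.0)
        with pytest.raises(ValueError):
            mac_filter(report_from_r(np.eye(3), "ABC"), cutoff=0.0)

    def test_mac_tie_drops_later_column(self):
        """Exact MAC tie within the offending pair: the variable later in
        column order is removed."""
        r = np.array([
            [1.0, 0.9, 0.3],
            [0.9, 1.0, 0.3],
            [0.3, 0.3, 1.0],
        ])
        survivors, log = mac_filter(report_from_r(r, "ABC"), cutoff=0.8)
        assert survivors == ["A", "C"]
        assert log[0].removed == "B"
        assert log[0].tie_broken

    def test_protected_names_never_removed(self):
        r = np.array([[1.0, 0.9, 0.85], [0.9, 1.0, 0.1], [0.85, 0.1, 1.0]])
        survivors, log = mac_filter(report_from_r(r, "ABC"), cutoff=0.8,
                                    protected={"A"})
        assert "A" in survivors
        with pytest.raises(KeyError):
            mac_filter(report_from_r(r, "ABC"), cutoff=0.8, protected={"Z"})

    @pytest.mark.parametrize("method", ["exact", "greedy"])
    def test_postcondition_no_surviving_pair(self, method):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(60, 3))
        table = pd.DataFrame(
            base @ rng.normal(size=(3, 8)) + 0.4 * rng.normal(size=(60, 8)),
            columns=[f"v{i}" for i in range(8)],
        )
        report = correlation_report(table)
        survivors, _ = mac_filter(report, cutoff=0.6, method=method)
        sub = report.r.loc[survivors, survivors].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.6

    def test_matches_reference_trace_on_random_datasets(self):
        """The implementation agrees with an exhaustive re-trace of the
        elimination rule on 200 seeded datasets of up to 6 variables."""
        for seed in range(200):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 7))
            n = 40
            latent = rng.normal(size=(n, max(1, k // 2)))
            data = latent @ rng.normal(size=(latent.shape[1], k))
            data += rng.uniform(0.2, 1.0) * rng.normal(size=(n, k))
            table = pd.DataFrame(data, columns=[f"v{i}" for i in range(k)])
            report = correlation_report(table)
            cutoff = float(rng.uniform(0.3, 0.9))
            survivors, _ = mac_filter(report, cutoff=cutoff)
            assert survivors == reference_elimination(report.r, cutoff), seed

    def test_planted_structure_keeps_only_clean_indices(self):
        """29 noisy affine copies of two latent factors plus the 2 clean
        factors: elimination at 0.8 removes every copy and keeps exactly
        the clean pair (the qualitative 31 → 2 reduction)."""
        panel, clean = make_collinear_panel(seed=5)
        report = correlation_report(panel)
        survivors, log = mac_filter(report, cutoff=0.8)
        assert sorted(survivors) == sorted(clean)
        assert len(log) == 29
        # and the clean pair is itself weakly correlated
        assert abs(report.r.loc[clean[0], clean[1]]) < 0.8


class TestSelectPredictors:
    def test_four_predictor_outcome(self):
        """CC and PH are kept unconditionally; with the planted panel the
        filter keeps 2 VIs → 4 predictors in total."""
        panel, clean = make_collinear_panel(seed=6)
        rng = np.random.default_rng(6)
        panel["CC"] = rng.uniform(0, 100, len(panel))
        panel["PH"] = rng.uniform(0, 1, len(panel))
        vi_names = [c for c in panel.columns if c not in ("CC", "PH")]
        result = select_predictors(panel, vi_names, cutoff=0.8)
        assert result.retained == ["CC", "PH"] + clean
        assert len(result.retained) == 4
        # eliminated VI columns are dropped from the table
        assert set(result.table.columns) == {"CC", "PH", *clean}

    def test_empty_vi_list(self):
        table = pd.DataFrame({"CC": [1.0, 2.0, 3.0], "PH": [0.1, 0.2, 0.3]})
        result = select_predictors(table, [], cutoff=0.8)
        assert result.retained == ["CC", "PH"]
        assert result.log == []

    def test_vacuous_cutoff_keeps_all(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(30, 5)),
                             columns=["CC", "PH", "a", "b", "c"])
        result = select_predictors(table, ["a", "b", "c"], cutoff=0.999999)
        assert result.retained == ["CC", "PH", "a", "b", "c"]

    def test_missing_column_rejected(self):
        table = pd.DataFrame({"CC": [1.0, 2.0]})
        with pytest.raises(KeyError):
            select_predictors(table, ["NDVI"])
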