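"""Regression metrics, model fitting, cross-validation and importance."""

import numpy as np
import pandas as pd
import pytest

from uavbiomass.models import (
    CVScheme,
    ModelSpec,
    fit,
    importance,
    lgocv,
    metrics,
    residual_summary,
)


def linear_table(n=120, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0.1, 1.0, n)
    gci = rng.uniform(1.0, 6.0, n)
    fb = 2.0 * ph + 3.0 * gci / 6.0 + noise * rng.standard_normal(n)
    return pd.DataFrame({"PH": ph, "GCI": gci, "CC": rng.uniform(20, 100, n),
                         "fb_measured": fb})


class TestMetrics:
    def test_identity(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == pytest.approx((1.0, 0.0, 0.0))

    def test_hand_computed_vector(self):
        m = metrics([1.0, 2.0, 3.0], [1.5, 2.0, 2.5])
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0 / 3.0)
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 6.0))

    def test_constant_shift(self):
        """R² is the squared correlation, hence shift-invariant; MAE and
        RMSE both equal the shift."""
        actual = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(actual, actual + 0.7)
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == pytest.approx(0.7)
        assert m.rmse == pytest.approx(0.7)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            actual = rng.normal(size=n)
            predicted = actual + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
            m = metrics(actual, predicted)
            assert m.mae <= m.rmse + 1e-12

    def test_r2_affine_invariance_of_predictions(self):
        rng = np.random.default_rng(1)
        actual = rng.normal(size=50)
        predicted = actual + 0.3 * rng.normal(size=50)
        base = metrics(actual, predicted)
        trans = metrics(actual, 2.5 * predicted - 1.0)
        assert trans.r2 == pytest.approx(base.r2)
        assert trans.mae != pytest.approx(base.mae)

    def test_zero_variance_flags_r2_only(self):
        m = metrics([1.0, 1.0, 1.0], [0.5, 1.0, 1.5])
        assert np.isnan(m.r2)
        assert m.mae == pytest.approx(1.0 / 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0, 2.0], [1.0])


class TestFit:
    def test_rf_memorizes_exact_signal(self):
        table = linear_table(seed=2)
        table["fb_measured"] = table["PH"]
        model = fit(ModelSpec("rf", seed=0), table, ["PH", "GCI", "CC"])
        resid = table["fb_measured"] - model.predict(table)
        assert np.sqrt((resid**2).mean()) < 0.05 * table["fb_measured"].std()

    def test_plsr_exact_linear_model_needs_two_components(self):
        table = linear_table(noise=1e-6, seed=3)
        model = fit(ModelSpec("plsr", plsr_max_lv=3, seed=0), table, ["PH", "GCI"])
        assert model.n_components <= 2
        resid = table["fb_measured"] - model.predict(table)
        assert np.abs(resid).max() < 1e-4

    def test_seed_determinism(self):
        table = linear_table(noise=0.3, seed=4)
        a = fit(ModelSpec("rf", seed=9), table, ["PH", "GCI", "CC"]).predict(table)
        b = fit(ModelSpec("rf", seed=9), table, ["PH", "GCI", "CC"]).predict(table)
        assert np.array_equal(a, b)

    def test_missing_values_rejected(self):
        table = linear_table(seed=5)
        table.loc[3, "PH"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit(ModelSpec("rf", rf_mtry=2), table, ["PH", "GCI"])

    def test_mtry_clipped_with_warning(self):
        table = linear_table(seed=6)
        with pytest.warns(UserWarning, match="clipped"):
            fit(ModelSpec("rf", rf_mtry=10, rf_ntree=20), table, ["PH", "GCI"])

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("ann")


class TestLgocv:
    def test_small_table_rejected(self):
        with pytest.raises(ValueError, match="cross-validation"):
            lgocv(ModelSpec("rf"), linear_table(n=9), ["PH"])

    def test_single_repeat_equals_manual_trace(self):
        """repeats=1 must reproduce a manual split-fit-predict by hand."""
        from sklearn.model_selection import ShuffleSplit

        table = linear_table(noise=0.2, seed=7)
        spec = ModelSpec("rf", rf_ntree=50, seed=21)
        scheme = CVScheme(repeats=1, seed=21)
        report = lgocv(spec, table, ["PH", "GCI", "CC"], scheme)

        tr, te = next(ShuffleSplit(n_splits=1, train_size=0.7, random_state=21)
                      .split(np.zeros(len(table))))
        model = fit(spec, table.iloc[tr], ["PH", "GCI", "CC"])
        manual = metrics(table.iloc[te]["fb_measured"], model.predict(table.iloc[te]))
        assert report.r2 == pytest.approx(manual.r2)
        assert report.mae == pytest.approx(manual.mae)
        assert report.rmse == pytest.approx(manual.rmse)

    def test_split_is_disjoint(self):
        table = linear_table(noise=0.2, seed=8)
        report = lgocv(ModelSpec("rf", rf_ntree=20, rf_mtry=2, seed=0), table,
                       ["PH", "GCI"], CVScheme(repeats=3, seed=0))
        for _, grp in report.predictions.groupby("repeat"):
            assert len(grp) == len(table) - int(0.7 * len(table))
            assert grp["row"].is_unique

    def test_full_determinism(self):
        table = linear_table(noise=0.2, seed=9)
        kwargs = dict(spec=ModelSpec("rf", rf_ntree=30, seed=5), table=table,
                      predictors=["PH", "GCI", "CC"], scheme=CVScheme(repeats=3, seed=5))
        a, b = lgocv(**kwargs), lgocv(**kwargs)
        assert a.per_repeat.equals(b.per_repeat)
        assert a.predictions.equals(b.predictions)
        assert a.importance == b.importance

    def test_mae_bounded_by_rmse_per_repeat(self):
        table = linear_table(noise=0.3, seed=10)
        report = lgocv(ModelSpec("rf", rf_ntree=30, rf_mtry=2, seed=1), table,
                       ["PH", "GCI"], CVScheme(repeats=5, seed=1))
        assert (report.per_repeat["mae"] <= report.per_repeat["rmse"] + 1e-12).all()

    def test_metrics_degrade_monotonically_with_noise(self):
        """In-sample recovery is near-perfect without noise; CV error
        grows with the observation-noise SD."""
        maes = []
        for noise in (0.0, 0.2, 0.6):
            table = linear_table(n=150, noise=noise, seed=11)
            if noise == 0.0:
                model = fit(ModelSpec("rf", rf_mtry=2, seed=2), table, ["PH", "GCI"])
                m = metrics(table["fb_measured"], model.predict(table))
                assert m.r2 >= 0.99
            report = lgocv(ModelSpec("rf", rf_ntree=100, rf_mtry=2, seed=2), table,
                           ["PH", "GCI"], CVScheme(repeats=3, seed=2))
            maes.append(report.mae)
        assert maes[0] < maes[1] < maes[2]


class TestImportance:
    def test_single_predictor_is_100(self):
        table = linear_table(noise=0.1, seed=12)
        model = fit(ModelSpec("rf", rf_ntree=50, rf_mtry=1, seed=0), table, ["PH"])
        assert importance(model, table)["PH"] == pytest.approx(100.0)

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({
            "PH": rng.uniform(0, 1, 150),
            "noise1": rng.normal(size=150),
            "noise2": rng.normal(size=150),
        })
        table["fb_measured"] = table["PH"] + 0.01 * rng.standard_normal(150)
        for algo in ("rf", "plsr"):
            model = fit(ModelSpec(algo, rf_ntree=100, seed=3), table,
                        ["PH", "noise1", "noise2"])
            imp = importance(model, table)
            assert imp["PH"] == 100.0
            assert imp["PH"] > imp["noise1"] and imp["PH"] > imp["noise2"]

    def test_max_is_pinned_to_100(self, rf_evaluation):
        assert max(rf_evaluation.importance.values()) == pytest.approx(100.0)

    def test_rank_stability_across_seeds(self):
        """Importance rank order on a structured table is stable across
        refits with different seeds (Kendall τ ≥ 0.6 between runs)."""
        from scipy.stats import kendalltau

        table = linear_table(n=150, noise=0.1, seed=14)
        orders = []
        for seed in range(5):
            model = fit(ModelSpec("rf", rf_ntree=100, seed=seed), table,
                        ["PH", "GCI", "CC"])
            imp = importance(model, table)
            orders.append([imp[c] for c in ("PH", "GCI", "CC")])
        for other in orders[1:]:
            tau = kendalltau(orders[0], other).statistic
            assert tau >= 0.6


class TestResidualSummary:
    def test_zero_residuals(self):
        table = linear_table(seed=15)
        report = lgocv(ModelSpec("rf", rf_ntree=20, rf_mtry=2, seed=0), table, ["PH", "GCI"],
                       CVScheme(repeats=2, seed=0))
        report.predictions["predicted"] = report.predictions["actual"]
        out = residual_summary(report, seed=0)
        assert out.sd == 0.0
        assert out.ci_lo == 0.0 and out.ci_hi == 0.0

    def test_two_point_sd(self):
        table = linear_table(seed=16)
        report = lgocv(ModelSpec("rf", rf_ntree=20, rf_mtry=2, seed=0), table, ["PH", "GCI"],
                       CVScheme(repeats=2, seed=0))
        report.predictions.drop(report.predictions.index[2:], inplace=True)
        report.predictions["actual"] = [0.0, 0.0]
        report.predictions["predicted"] = [1.0, -1.0]
        assert residual_summary(report, seed=0).sd == pytest.approx(np.sqrt(2.0))

    def test_rf_beats_plsr_on_nonlinear_truth(self):
        """When biomass is strongly nonlinear in height, the forest's
        pooled residual SD beats the linear PLSR's in ≥ 8 of 10 seeded
        replicates."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            ph = rng.uniform(0.0, 1.0, 120)
            gci = rng.uniform(1.0, 6.0, 120)
            fb = np.where(ph > 0.5, 3.0 * ph, 0.2 * ph) + 0.05 * rng.standard_normal(120)
            table = pd.DataFrame({"PH": ph, "GCI": gci, "fb_measured": fb})
            scheme = CVScheme(repeats=5, seed=seed)
            rf = lgocv(ModelSpec("rf", rf_ntree=200, rf_mtry=2, seed=seed), table, ["PH", "GCI"], scheme)
            pl = lgocv(ModelSpec("plsr", seed=seed), table, ["PH", "GCI"], scheme)
            wins += residual_summary(rf, seed=0).sd <= residual_summary(pl, seed=0).sd
        assert wins >= 8
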