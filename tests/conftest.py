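"""Shared fixtures: one calibration trial and one screening trial per
session, generated by the package's own synthetic-field module."""

import pytest

from uavbiomass import models, pipeline, screening, synthetic


@pytest.fixture(scope="session")
def calibration_trial():
    """Default two-year calibration trial (90 plots, 9 flight GDDs)."""
    return synthetic.make_trial(synthetic.default_calibration_design(seed=11))


@pytest.fixture(scope="session")
def calibration_table(calibration_trial):
    """Plots × predictors modelling table with the full 31-index panel."""
    return pipeline.build_predictor_table(calibration_trial)


FOUR_PREDICTORS = ["CC", "PH", "TGI", "GCI"]


@pytest.fixture(scope="session")
def rf_evaluation(calibration_table):
    """RF LGOCV (70/30 × 10) on the four headline predictors."""
    return models.lgocv(
        models.ModelSpec("rf", seed=17),
        calibration_table,
        FOUR_PREDICTORS,
        models.CVScheme(seed=17),
    )


@pytest.fixture(scope="session")
def rf_model(calibration_table):
    return models.fit(models.ModelSpec("rf", seed=17), calibration_table, FOUR_PREDICTORS)


@pytest.fixture(scope="session")
def screening_predictions(rf_model):
    """Early/late × drought/control screening panel scored by the RF."""
    design = synthetic.default_screening_design(seed=13)
    trial = synthetic.make_trial(design)
    table = pipeline.build_predictor_table(trial)
    return screening.predict_screening(rf_model, table)
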