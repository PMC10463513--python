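"""Calibrate and cross-validate the fresh-biomass models.

Random forest (500 trees, mtry=3) and PLSR (latent variables by inner-CV
RMSE) predict measured fresh biomass from four predictors — canopy cover,
plant height, TGI and GCI — under leave-group-out cross-validation:
10 repeats of a random 70/30 plot split, metrics averaged over repeats.
R² is the squared Pearson correlation between actual and predicted.
"""

from uavbiomass import models, pipeline, synthetic

trial = synthetic.make_trial(synthetic.default_calibration_design(seed=42))
table = pipeline.build_predictor_table(trial)
predictors = ["CC", "PH", "TGI", "GCI"]

for algo in ("rf", "plsr"):
    ev = models.lgocv(models.ModelSpec(algo, seed=1), table, predictors,
                      models.CVScheme(seed=1))
    sd = models.residual_summary(ev, seed=1)
    print(f"{algo.upper():4s}  R²={ev.r2:.3f}  MAE={ev.mae:.3f}  "
          f"RMSE={ev.rmse:.3f} kg/m²  residual SD={sd.sd:.3f} "
          f"[{sd.ci_lo:.3f}, {sd.ci_hi:.3f}]")
    print(f"      importance (0-100): "
          + "  ".join(f"{k}={v:.0f}" for k, v in ev.importance.items()))

floor = synthetic.noise_floor_mae()
print(f"\ngenerative noise floor: E|ε| = {floor:.3f} kg/m² — no model can")
print("average below it; both models sit close, so most of the planted")
print("signal is recovered. Plant height dominates the importance ranking.")
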