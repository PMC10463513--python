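"""End-to-end orchestration: simulate → extract → indices → filter →
train → screen, with a reproducible run manifest.

Every stage is an ordinary library call; this module wires them together,
derives one sub-seed per stage from the master seed, and records a
manifest (stage, seed, wall time, output file hashes) so any numeric
output is traceable to (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import filtering, indices, models, screening, synthetic, traits

__all__ = [
    "METADATA_COLUMNS",
    "stage_seed",
    "extract_table",
    "build_predictor_table",
    "default_config",
    "validate_config",
    "run_pipeline",
]

#: Columns of a predictor table that are never predictors.
METADATA_COLUMNS = (
    "obs_id", "plot_id", "genotype", "maturity", "year", "rep", "gdd",
    "environment", "fb_true", "fb_measured", "cc_true", "ph_true", "trial",
    "fb_pred",
)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: master seed + stage name hashed
    through numpy's SeedSequence, reduced below 2^31."""
    digest = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31))


def extract_table(
    manifest: pd.DataFrame,
    rasters: Mapping[str, synthetic.RenderedPlot],
    rule: traits.MaskRule = traits.MaskRule(),
    rois: Mapping[str, traits.ROI] | None = None,
) -> pd.DataFrame:
    """Run trait extraction for every observation of a trial.

    ROIs default to the full plot frame. Returns the manifest joined with
    CC (%), PH (m) and mean DN columns.
    """
    rows = []
    for _, meta in manifest.iterrows():
        obs_id = meta["obs_id"]
        plot = rasters[obs_id]
        roi = (rois or {}).get(obs_id) or traits.ROI.full(plot.stack.shape)
        mask = traits.mask_soil(plot.stack, rule)
        row = meta.to_dict()
        row["CC"] = traits.canopy_cover(mask, roi)
        row["PH"] = traits.plant_height(plot.elevation, mask, roi)
        dns = traits.mean_dns(plot.stack, mask, roi)
        row.update({f"dn_{b}": v for b, v in zip(traits.BANDS, dns)})
        rows.append(row)
    return pd.DataFrame(rows)


def build_predictor_table(
    trial: synthetic.Trial,
    rule: traits.MaskRule = traits.MaskRule(),
    registry: indices.IndexRegistry | None = None,
) -> pd.DataFrame:
    """Extract traits and attach the vegetation-index panel — the plots ×
    predictors modelling table."""
    table = extract_table(trial.manifest, trial.rasters, rule)
    return indices.attach_panel(table, registry)


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "mask": {"rule": "ndvi", "threshold": 0.4},
        "registry": None,              # path to a YAML registry; None = packaged
        "cutoff": 0.8,
        "keep": ["CC", "PH"],
        "model": {"algorithm": "rf", "rf_ntree": 500, "rf_mtry": 3, "plsr_max_lv": 10},
        "cv": {"train_fraction": 0.7, "repeats": 10},
        "design": {},                  # TrialDesign overrides for calibration
        "screening": {"enabled": True, "n_early": 32, "n_late": 32},
        "write_rasters": False,
    }


def validate_config(config: Mapping) -> dict:
    """Merge over defaults and fail fast on unknown keys or bad values,
    before any stage runs."""
    cfg = default_config()
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in config.items():
        if isinstance(cfg[key], dict) and isinstance(value, Mapping):
            bad = set(value) - set(cfg[key]) if key != "design" else set()
            if bad:
                raise ValueError(f"unknown config keys under {key!r}: {sorted(bad)}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    traits.MaskRule(cfg["mask"]["rule"], cfg["mask"]["threshold"])
    if not 0.0 < cfg["cutoff"] < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if cfg["registry"] is not None and not Path(cfg["registry"]).exists():
        raise FileNotFoundError(f"registry file not found: {cfg['registry']}")
    models.ModelSpec(algorithm=cfg["model"]["algorithm"],
                     rf_ntree=cfg["model"]["rf_ntree"],
                     rf_mtry=cfg["model"]["rf_mtry"],
                     plsr_max_lv=cfg["model"]["plsr_max_lv"])
    models.CVScheme(train_fraction=cfg["cv"]["train_fraction"],
                    repeats=cfg["cv"]["repeats"])
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Execute all stages and write artifacts plus ``manifest.json``.

    Returns a dict with the key artifacts (paths and in-memory results).
    Raises before any stage runs if the config does not validate.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    registry = (
        indices.IndexRegistry.from_yaml(cfg["registry"])
        if cfg["registry"] else indices.default_registry()
    )
    rule = traits.MaskRule(cfg["mask"]["rule"], cfg["mask"]["threshold"])
    run_manifest: list[dict] = []

    def record(stage: str, seed: int, t0: float, outputs: Sequence[Path]) -> None:
        run_manifest.append({
            "stage": stage,
            "seed": seed,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        })

    # simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    seed_sim = stage_seed(master, "simulate")
    design = synthetic.default_calibration_design(seed=seed_sim, **cfg["design"])
    trial = synthetic.make_trial(design)
    sim_out = [outdir / "calibration_manifest.csv"]
    trial.manifest.to_csv(sim_out[0], index=False)
    if cfg["write_rasters"]:
        sim_out.append(synthetic.write_trial(trial, outdir / "rasters"))
        sim_out[-1] = outdir / "rasters" / "manifest.csv"
    record("simulate", seed_sim, t0, sim_out)

    # extract + indices ------------------------------------------------
    t0 = time.perf_counter()
    table = extract_table(trial.manifest, trial.rasters, rule)
    plots_path = outdir / "plots.csv"
    table.to_csv(plots_path, index=False)
    record("extract", seed_sim, t0, [plots_path])

    t0 = time.perf_counter()
    table = indices.attach_panel(table, registry)
    vi_path = outdir / "plots_vi.csv"
    table.to_csv(vi_path, index=False)
    record("indices", seed_sim, t0, [vi_path])

    # filter -----------------------------------------------------------
    t0 = time.perf_counter()
    vi_names = [n for n in registry.names if n in table.columns]
    selection = filtering.select_predictors(
        table, vi_names, always_keep=cfg["keep"], cutoff=cfg["cutoff"]
    )
    report = filtering.correlation_report(table, vi_names)
    reduced_path = outdir / "reduced.csv"
    selection.table.to_csv(reduced_path, index=False)
    corr_path = outdir / "correlation.csv"
    report.r.to_csv(corr_path)
    heatmap_path = outdir / "correlation.png"
    filtering.plot_correlation(report, heatmap_path)
    log_path = outdir / "removals.json"
    log_path.write_text(json.dumps([
        {"pair": s.pair, "r": s.r, "mac": s.mac, "removed": s.removed,
         "tie_broken": s.tie_broken}
        for s in selection.log
    ], indent=2))
    record("filter", seed_sim, t0, [reduced_path, corr_path, log_path])

    # train ------------------------------------------------------------
    t0 = time.perf_counter()
    seed_train = stage_seed(master, "train")
    spec = models.ModelSpec(
        algorithm=cfg["model"]["algorithm"], rf_ntree=cfg["model"]["rf_ntree"],
        rf_mtry=cfg["model"]["rf_mtry"], plsr_max_lv=cfg["model"]["plsr_max_lv"],
        seed=seed_train,
    )
    scheme = models.CVScheme(
        train_fraction=cfg["cv"]["train_fraction"], repeats=cfg["cv"]["repeats"],
        seed=seed_train,
    )
    evaluation = models.lgocv(spec, selection.table, selection.retained, scheme)
    resid = models.residual_summary(evaluation, seed=seed_train)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps({
        "schema_version": 1,
        "algorithm": spec.algorithm,
        "predictors": list(selection.retained),
        "r2": evaluation.r2, "mae": evaluation.mae, "rmse": evaluation.rmse,
        "residual_sd": evaluation.residual_sd,
        "residual_sd_pooled": resid.sd,
        "residual_sd_ci": [resid.ci_lo, resid.ci_hi],
        "per_repeat": evaluation.per_repeat.to_dict(orient="records"),
        "importance": evaluation.importance,
        "rf_details": {"split_criterion": "variance reduction",
                       "max_depth": None, "bootstrap": True},
        "seed": seed_train,
    }, indent=2))
    preds_path = outdir / "predictions.csv"
    evaluation.predictions.to_csv(preds_path, index=False)
    record("train", seed_train, t0, [report_path, preds_path])

    # screen -----------------------------------------------------------
    screen_results = None
    if cfg["screening"]["enabled"]:
        t0 = time.perf_counter()
        seed_screen = stage_seed(master, "screen")
        sdesign = synthetic.default_screening_design(
            seed=seed_screen, n_early=cfg["screening"]["n_early"],
            n_late=cfg["screening"]["n_late"],
        )
        strial = synthetic.make_trial(sdesign)
        stable = build_predictor_table(strial, rule, registry)
        model = models.fit(spec, selection.table, selection.retained)
        predicted = screening.predict_screening(model, stable)
        groups = screening.group_summary(predicted, seed=seed_screen)
        contrasts = screening.drought_contrast(predicted, seed=seed_screen)
        groups_path = outdir / "screening_groups.csv"
        groups.drop(columns=["outliers"]).to_csv(groups_path, index=False)
        contrasts_path = outdir / "drought_contrasts.csv"
        contrasts.to_csv(contrasts_path, index=False)
        record("screen", seed_screen, t0, [groups_path, contrasts_path])
        screen_results = {"groups": groups, "contrasts": contrasts}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(run_manifest, indent=2))
    return {
        "outdir": outdir,
        "manifest": run_manifest,
        "predictor_table": table,
        "selection": selection,
        "evaluation": evaluation,
        "screening": screen_results,
    }
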