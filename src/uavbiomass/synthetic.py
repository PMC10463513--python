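"""Seeded synthetic field trials with the structure of a UAV biomass study.

The generator emulates a two-year soybean calibration/screening experiment:
genotypes × replicates laid out as small plots, each photographed as a
5-band multispectral raster (B, G, R, RE, NIR digital numbers) plus a
DSM/DTM elevation pair, at several growing-degree-day (GDD) time points,
optionally under a drought environment.

Ground truth per plot — fresh biomass (FB, kg/m²), plant height (PH, m)
and canopy cover (CC, fraction) — follows a logistic growth curve in GDD
with an allometric height law and a saturating cover law. Drought
depresses the biomass asymptote and shifts plant reflectance (visible up,
NIR down); both effects ramp in with a logistic onset so that early
development is essentially unaffected, as observed in drought trials.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import BANDS, ChannelStack, ElevationPair

__all__ = [
    "GrowthParams",
    "SpectraParams",
    "TrialDesign",
    "RenderedPlot",
    "Trial",
    "growth_curve",
    "drought_stress",
    "render_plot",
    "make_trial",
    "write_trial",
    "read_trial",
    "default_calibration_design",
    "default_screening_design",
    "make_collinear_panel",
    "noise_floor_mae",
]

_ENVIRONMENTS = ("control", "drought")


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the generative growth model.

    Defaults are calibrated so the control trajectory passes through the
    observed seasonal anchors FB ≈ 0.18 kg/m² at 274 GDD and
    FB ≈ 3.03 kg/m² at 1016 GDD, with PH ≈ 0.15/0.99 m at the same points.
    """

    fb_max: float = 3.8           # kg/m², biomass asymptote
    gdd_mid: float = 783.0        # °C·days at the logistic inflection
    gdd_rate: float = 0.0059      # 1/(°C·days)
    ph_per_fb: float = 0.472      # m per (kg/m²)^ph_exp
    ph_exp: float = 0.67          # allometric exponent, unitless
    cc_half: float = 0.30         # kg/m² biomass at 50% canopy cover
    noise_sd_fb: float = 0.15     # kg/m², additive noise on measured FB
    noise_sd_ph: float = 0.02     # m, additive plot-level height noise
    drought_factor: float = 0.6   # asymptote multiplier under full drought
    drought_onset_gdd: float = 500.0  # °C·days at 50% stress expression
    drought_onset_rate: float = 0.02  # 1/(°C·days)

    def __post_init__(self) -> None:
        if self.fb_max <= 0 or self.gdd_rate <= 0:
            raise ValueError("fb_max and gdd_rate must be positive")
        if not 0.0 < self.drought_factor <= 1.0:
            raise ValueError("drought_factor must lie in (0, 1]")
        if self.noise_sd_fb < 0 or self.noise_sd_ph < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SpectraParams:
    """Mean plant/soil digital numbers per band and their modifiers.

    Digital numbers are unitless reflectance-like values in [0, 1];
    radiometric calibration is assumed already applied by the sensor's sun
    sensor and is not simulated.
    """

    plant_dn: tuple[float, ...] = (0.04, 0.08, 0.05, 0.25, 0.45)
    soil_dn: tuple[float, ...] = (0.10, 0.14, 0.16, 0.20, 0.22)
    dn_sd: float = 0.01              # per-band pixel noise SD
    chlorophyll_scale: float = 0.2   # couples canopy density to G/NIR
    drought_vis_gain: float = 1.15   # visible-band multiplier, >= 1
    drought_nir_loss: float = 0.90   # NIR/RE multiplier, <= 1
    elev_noise_sd: float = 0.02      # m, per-pixel DSM noise on canopy
    dtm_relief: float = 0.05         # m, amplitude of the smooth terrain

    def __post_init__(self) -> None:
        plant = np.asarray(self.plant_dn, float)
        soil = np.asarray(self.soil_dn, float)
        if plant.shape != (5,) or soil.shape != (5,):
            raise ValueError("plant_dn and soil_dn must be 5-vectors (B,G,R,RE,NIR)")
        if np.any(plant < 0) or np.any(soil < 0):
            raise ValueError("digital numbers must be >= 0")
        b = dict(zip(BANDS, plant))
        s = dict(zip(BANDS, soil))
        if b["NIR"] <= b["R"]:
            raise ValueError("plant NIR DN must exceed plant R DN")
        if abs(s["NIR"] - s["R"]) >= abs(b["NIR"] - b["R"]):
            raise ValueError("soil spectrum must be flatter than plant spectrum")
        if self.drought_vis_gain < 1 or self.drought_nir_loss > 1:
            raise ValueError("drought multipliers must brighten visible and dim NIR")


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a synthetic trial.

    ``gdd_points`` maps year → strictly increasing flight GDDs;
    ``maturity_group`` maps genotype name → 'early' | 'late' (defaults to
    alternating assignment when omitted).
    """

    n_genotypes: int = 10
    reps_by_year: Mapping[int, int] = field(
        default_factory=lambda: {2020: 5, 2021: 4}
    )
    gdd_points: Mapping[int, Sequence[float]] = field(
        default_factory=lambda: {2020: (274, 413, 650, 745, 1016), 2021: (215, 492, 747, 1130)}
    )
    environments: tuple[str, ...] = ("control",)
    maturity_group: Mapping[str, str] | None = None
    plot_shape: tuple[int, int] = (48, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("need at least one genotype")
        if not self.environments:
            raise ValueError("environments must be a non-empty subset of "
                             f"{_ENVIRONMENTS}")
        for env in self.environments:
            if env not in _ENVIRONMENTS:
                raise ValueError(f"unknown environment {env!r}")
        if set(self.reps_by_year) != set(self.gdd_points):
            raise ValueError("reps_by_year and gdd_points must cover the same years")
        for year, pts in self.gdd_points.items():
            if len(pts) == 0:
                raise ValueError(f"year {year} has no GDD time points")
            if np.any(np.diff(np.asarray(pts, float)) <= 0):
                raise ValueError(f"gdd_points for {year} must be strictly increasing")
        if min(self.plot_shape) < 8:
            raise ValueError("plot_shape must be at least 8×8 pixels")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1:02d}" for i in range(self.n_genotypes))

    def maturity(self, genotype: str) -> str:
        if self.maturity_group is not None:
            return self.maturity_group[genotype]
        idx = self.genotypes.index(genotype)
        return "early" if idx % 2 == 0 else "late"

    @property
    def n_plots(self) -> int:
        """Number of physical plots (genotype × rep × year × environment)."""
        return (
            self.n_genotypes
            * sum(self.reps_by_year.values())
            * len(self.environments)
        )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def drought_stress(gdd, params: GrowthParams):
    """Fraction of full drought expression at a given GDD, in [0, 1].

    Water deficit barely affects early vegetative growth; damage grows
    after flowering. Modelled as a logistic ramp centred on
    ``drought_onset_gdd``.
    """
    return _sigmoid(params.drought_onset_rate * (np.asarray(gdd, float) - params.drought_onset_gdd))


def growth_curve(gdd, params: GrowthParams = GrowthParams(), environment: str = "control"):
    """Noiseless (FB kg/m², PH m, CC fraction) at thermal time ``gdd``.

    FB follows a logistic in GDD; under drought the asymptote is scaled by
    an effective factor that ramps from 1 toward ``drought_factor`` as the
    stress expresses. PH = ph_per_fb·FB^ph_exp, CC = FB/(FB + cc_half);
    all three are non-decreasing in GDD.
    """
    gdd = np.asarray(gdd, dtype=float)
    if np.any(gdd < 0):
        raise ValueError("gdd must be >= 0")
    if environment not in _ENVIRONMENTS:
        raise ValueError(f"unknown environment {environment!r}")
    fb_eff = params.fb_max
    if environment == "drought":
        fb_eff = params.fb_max * (
            1.0 - (1.0 - params.drought_factor) * drought_stress(gdd, params)
        )
    fb = fb_eff * _sigmoid(params.gdd_rate * (gdd - params.gdd_mid))
    ph = params.ph_per_fb * fb ** params.ph_exp
    cc = fb / (fb + params.cc_half)
    if gdd.ndim == 0:
        return float(fb), float(ph), float(cc)
    return fb, ph, cc


@dataclass(frozen=True)
class RenderedPlot:
    """One simulated plot: 5-band stack, elevation pair and the true
    plant/soil label grid (kept for masking-accuracy checks)."""

    stack: ChannelStack
    elevation: ElevationPair
    plant_mask: np.ndarray


def _smooth_terrain(shape: tuple[int, int], relief: float, rng: np.random.Generator) -> np.ndarray:
    """Low-relief smooth terrain: two random low-frequency sine waves."""
    rows, cols = shape
    y = np.linspace(0.0, 1.0, rows)[:, None]
    x = np.linspace(0.0, 1.0, cols)[None, :]
    f1, f2 = rng.uniform(0.5, 1.5, size=2)
    p1, p2 = rng.uniform(0.0, 2.0 * math.pi, size=2)
    return relief * np.sin(2 * math.pi * f1 * x + p1) * np.sin(2 * math.pi * f2 * y + p2)


def render_plot(
    fb: float,
    cc: float,
    ph: float,
    spectra: SpectraParams = SpectraParams(),
    environment: str = "control",
    shape: tuple[int, int] = (48, 48),
    seed: int | np.random.Generator = 0,
    stress: float | None = None,
    clustered: bool = False,
) -> RenderedPlot:
    """Render one plot as rasters.

    A random pixel subset of expected fraction ``cc`` is plant; plant
    pixels take the plant spectrum (chlorophyll-coupled, drought-shifted),
    soil pixels the soil spectrum, both with additive Gaussian pixel noise.
    DSM = DTM + PH (+ elevation noise) on plant pixels, DSM = DTM on soil.

    ``stress`` scales the drought spectral shift (1 = fully expressed);
    ``clustered`` switches the plant field from i.i.d. Bernoulli to a
    smoothed-threshold field mimicking row structure.
    """
    if not 0.0 <= cc <= 1.0:
        raise ValueError("cc must lie in [0, 1]")
    if ph < 0:
        raise ValueError("ph must be >= 0")
    if environment not in _ENVIRONMENTS:
        raise ValueError(f"unknown environment {environment!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = shape

    if clustered:
        from scipy.ndimage import gaussian_filter

        fieldv = gaussian_filter(rng.standard_normal(shape), sigma=2.0, mode="wrap")
        thresh = np.quantile(fieldv, 1.0 - cc) if 0 < cc < 1 else (np.inf if cc == 0 else -np.inf)
        plant = fieldv > thresh
    else:
        plant = rng.random(shape) < cc

    # Effective plant spectrum: canopy density nudges NIR/RE up and G down
    # (denser, greener canopy), drought brightens visible and dims NIR/RE.
    plant_dn = np.asarray(spectra.plant_dn, float).copy()
    s = 1.0 + spectra.chlorophyll_scale * (cc - 0.5)
    plant_dn[[3, 4]] *= s       # RE, NIR
    plant_dn[1] /= s            # G
    if environment == "drought":
        w = 1.0 if stress is None else float(np.clip(stress, 0.0, 1.0))
        vis = 1.0 + (spectra.drought_vis_gain - 1.0) * w
        nir = 1.0 - (1.0 - spectra.drought_nir_loss) * w
        plant_dn[[0, 1, 2]] *= vis  # B, G, R
        plant_dn[[3, 4]] *= nir     # RE, NIR

    soil_dn = np.asarray(spectra.soil_dn, float)
    base = np.where(plant[None, :, :], plant_dn[:, None, None], soil_dn[:, None, None])
    noise = rng.normal(0.0, spectra.dn_sd, size=(5, rows, cols)) if spectra.dn_sd > 0 else 0.0
    stack = ChannelStack(np.clip(base + noise, 0.0, None))

    dtm = _smooth_terrain(shape, spectra.dtm_relief, rng)
    chm = np.zeros(shape)
    if spectra.elev_noise_sd > 0:
        chm[plant] = np.clip(ph + rng.normal(0.0, spectra.elev_noise_sd, size=int(plant.sum())), 0.0, None)
    else:
        chm[plant] = ph
    elevation = ElevationPair(dsm=dtm + chm, dtm=dtm)
    return RenderedPlot(stack=stack, elevation=elevation, plant_mask=plant)


@dataclass
class Trial:
    """A generated trial: per-observation manifest plus (optionally) the
    rendered rasters keyed by observation id."""

    manifest: pd.DataFrame
    rasters: dict[str, RenderedPlot]
    design: TrialDesign
    growth: GrowthParams
    spectra: SpectraParams


def make_trial(
    design: TrialDesign,
    growth: GrowthParams = GrowthParams(),
    spectra: SpectraParams = SpectraParams(),
    render: bool = True,
) -> Trial:
    """Generate a full trial: one observation per genotype × replicate ×
    year × GDD point × environment.

    Genotype random effects are multiplicative log-normal (SD 0.15) on the
    biomass asymptote; late-maturity genotypes get a larger asymptote
    (×1.2) and a later inflection (+40 GDD), so they accumulate more
    biomass over a longer season. Measured FB adds Gaussian noise
    (``noise_sd_fb``) to the latent plot biomass.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    genotypes = design.genotypes
    geno_mult = {g: float(m) for g, m in zip(genotypes, np.exp(rng.normal(0.0, 0.15, size=len(genotypes))))}

    rows = []
    rasters: dict[str, RenderedPlot] = {}
    for year in sorted(design.reps_by_year):
        n_rep = design.reps_by_year[year]
        for env in design.environments:
            for gi, genotype in enumerate(genotypes):
                maturity = design.maturity(genotype)
                gp = growth
                if maturity == "late":
                    gp = replace(gp, fb_max=gp.fb_max * 1.2, gdd_mid=gp.gdd_mid + 40.0)
                gp = replace(gp, fb_max=gp.fb_max * geno_mult[genotype])
                for rep in range(1, n_rep + 1):
                    plot_id = f"{year}_{env}_g{gi + 1:02d}_r{rep}"
                    for gdd in design.gdd_points[year]:
                        fb_true, ph_nom, cc_true = growth_curve(float(gdd), gp, env)
                        ph_true = max(0.0, ph_nom + rng.normal(0.0, gp.noise_sd_ph))
                        fb_measured = max(0.0, fb_true + rng.normal(0.0, gp.noise_sd_fb))
                        obs_id = f"{plot_id}_t{int(gdd)}"
                        stress = float(drought_stress(gdd, gp)) if env == "drought" else 0.0
                        rows.append(
                            dict(
                                obs_id=obs_id,
                                plot_id=plot_id,
                                genotype=genotype,
                                maturity=maturity,
                                year=year,
                                rep=rep,
                                gdd=float(gdd),
                                environment=env,
                                fb_true=fb_true,
                                fb_measured=fb_measured,
                                cc_true=float(np.clip(cc_true, 0.0, 1.0)),
                                ph_true=ph_true,
                            )
                        )
                        if render:
                            rasters[obs_id] = render_plot(
                                fb_true,
                                float(np.clip(cc_true, 0.0, 1.0)),
                                ph_true,
                                spectra,
                                environment=env,
                                shape=design.plot_shape,
                                seed=rng,
                                stress=stress,
                            )
    manifest = pd.DataFrame(rows)
    return Trial(manifest=manifest, rasters=rasters, design=design, growth=growth, spectra=spectra)


def default_calibration_design(seed: int = 0, **overrides) -> TrialDesign:
    """The calibration layout: 10 varieties × 5 reps (year 1) + 4 reps
    (year 2) = 90 plots, control environment, nine flight GDDs."""
    return TrialDesign(seed=seed, **overrides)


def default_screening_design(
    seed: int = 0,
    n_early: int = 32,
    n_late: int = 32,
    **overrides,
) -> TrialDesign:
    """Screening layout: early/late maturity panels under drought and
    control, photographed at ~230/390/706/917 GDD in both years."""
    n = n_early + n_late
    genotypes = tuple(f"G{i + 1:02d}" for i in range(n))
    maturity = {g: ("early" if i < n_early else "late") for i, g in enumerate(genotypes)}
    kwargs = dict(
        n_genotypes=n,
        reps_by_year={2020: 1, 2021: 1},
        gdd_points={2020: (230, 390, 706, 917), 2021: (230, 390, 706, 917)},
        environments=("drought", "control"),
        maturity_group=maturity,
        seed=seed,
    )
    kwargs.update(overrides)
    return TrialDesign(**kwargs)


def make_collinear_panel(
    n_samples: int = 300,
    block_sizes: tuple[int, int] = (15, 14),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic index panel with the collinearity structure of a real VI
    set: two clean, mutually independent indices ("F1", "F2") plus noisy
    affine copies of them ("V01".."V29" by default).

    Each copy loads on its factor (r ≈ 0.88 with it), shares a within-block
    nuisance component (so copies inter-correlate at ≈ 0.98, more strongly
    than with the factor itself) and carries a small cross-factor loading.
    Under mean-absolute-correlation elimination at cutoff 0.8 every copy is
    eventually paired against its factor and loses (larger MAC), so exactly
    the two clean indices survive — the qualitative 31 → 2 reduction.

    Returns (panel table, names of the two clean indices).
    """
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal((2, n_samples))
    h1, h2 = rng.standard_normal((2, n_samples))
    cols: dict[str, np.ndarray] = {"F1": f1.copy(), "F2": f2.copy()}
    k = 0
    for factor, other, nuisance, size in ((f1, f2, h1, block_sizes[0]),
                                          (f2, f1, h2, block_sizes[1])):
        for _ in range(size):
            k += 1
            a, b = rng.uniform(0.95, 1.05), rng.uniform(0.45, 0.55)
            noise = 0.15 * rng.standard_normal(n_samples)
            cols[f"V{k:02d}"] = a * factor + b * nuisance + 0.2 * other + noise
    return pd.DataFrame(cols), ["F1", "F2"]


def noise_floor_mae(growth: GrowthParams = GrowthParams()) -> float:
    """Expected MAE of a perfect model given the generator's additive FB
    observation noise: E|N(0, σ)| = σ·√(2/π)."""
    return growth.noise_sd_fb * math.sqrt(2.0 / math.pi)


def write_trial(trial: Trial, outdir: str | Path) -> Path:
    """Write a trial to disk: one single-band TIFF per channel plus
    DSM/DTM TIFFs per observation, and a CSV manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for obs_id, plot in trial.rasters.items():
        for bi, band in enumerate(BANDS):
            tifffile.imwrite(outdir / f"{obs_id}_{band}.tif", plot.stack.data[bi].astype(np.float32))
        tifffile.imwrite(outdir / f"{obs_id}_DSM.tif", plot.elevation.dsm.astype(np.float32))
        tifffile.imwrite(outdir / f"{obs_id}_DTM.tif", plot.elevation.dtm.astype(np.float32))
        tifffile.imwrite(outdir / f"{obs_id}_LABEL.tif", plot.plant_mask.astype(np.uint8))
    trial.manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_trial(indir: str | Path) -> tuple[pd.DataFrame, dict[str, RenderedPlot]]:
    """Load a written trial back: (manifest, rasters keyed by obs_id)."""
    import tifffile

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    rasters: dict[str, RenderedPlot] = {}
    for obs_id in manifest["obs_id"]:
        bands = {b: tifffile.imread(indir / f"{obs_id}_{b}.tif") for b in BANDS}
        dsm = tifffile.imread(indir / f"{obs_id}_DSM.tif")
        dtm = tifffile.imread(indir / f"{obs_id}_DTM.tif")
        label_path = indir / f"{obs_id}_LABEL.tif"
        label = tifffile.imread(label_path).astype(bool) if label_path.exists() else None
        rasters[obs_id] = RenderedPlot(
            stack=ChannelStack.from_bands(bands),
            elevation=ElevationPair(dsm=np.asarray(dsm, float), dtm=np.asarray(dtm, float)),
            plant_mask=label,
        )
    return manifest, rasters
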