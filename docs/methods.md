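# Methods

`uavbiomass` implements a complete desk-scale analogue of a UAV
multispectral biomass-phenotyping study: a seeded generator of synthetic
field trials, per-plot trait extraction, a vegetation-index panel,
correlation-based predictor pruning, random-forest and PLS regression
under repeated hold-out validation, and temporal drought screening. This
note records the models, the parameter choices and their rationale, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## The synthetic field trial

No raw imagery from the motivating field experiments is publicly
deposited, so every analysis stage is exercised on a generator that
reproduces the *statistical structure* the pipeline assumes rather than
any particular field.

**Growth model.** Per plot, fresh biomass (FB, kg/m²) follows a logistic
in thermal time (growing degree days, GDD):

    FB(g) = fb_eff / (1 + exp(−r·(g − g_mid)))

with height and cover tied to biomass allometrically:

    PH = a·FB^b          (a = 0.472 m·(kg/m²)^−b, b = 0.67)
    CC = FB / (FB + c)   (c = 0.30 kg/m²)

Defaults `fb_max = 3.8 kg/m²`, `r = 0.0059 /GDD`, `g_mid = 783 GDD` place
the control trajectory through two seasonal anchor states typical of a
soybean calibration trial — FB ≈ 0.18 kg/m², PH ≈ 0.15 m at 274 GDD and
FB ≈ 3.03 kg/m², PH ≈ 0.99 m at 1016 GDD. A single logistic cannot also
interpolate every mid-season mean; the anchors and the monotone sigmoid
shape are what the downstream tests rely on. All three trajectories are
non-decreasing in GDD by construction, and this is property-tested.

**Drought.** Drought multiplies the biomass asymptote by
`drought_factor` (default 0.6), but the stress *expresses gradually*: a
logistic onset (mid 500 GDD, rate 0.02/GDD) ramps the effective
multiplier from 1 to `drought_factor`. Soybean is insensitive to water
deficit in early vegetative growth and most damaged after flowering, so
at the first screening flight (~230 GDD) expression is <1% while after
~700 GDD it is essentially complete. The same onset weight scales the
drought spectral shift — visible reflectance up (×1.15 fully expressed),
NIR/red-edge down (×0.90) — so early-season drought plots are
spectrally indistinguishable from control, as they should be.

**Plots as rasters.** Each observation is rendered as a 5-band stack
(B, G, R, RE, NIR digital numbers, unitless reflectance-like values in
[0, 1]; radiometric calibration is assumed already applied by the
sensor's sun sensor) plus a DSM/DTM pair in metres. Pixels are plant
with i.i.d. Bernoulli(CC) probability (an optional smoothed-threshold
mode mimics row clustering; the i.i.d. default keeps the cover-recovery
tests analytically tractable). Plant and soil spectra are fixed
5-vectors chosen so the plant NIR−R contrast (0.40) dominates the soil
contrast (0.06) — NDVI ≈ 0.78 vs ≈ 0.16 — making threshold masking
well-posed; a chlorophyll coupling nudges G down and RE/NIR up with
canopy density so greenness indices carry biomass information. Per-pixel
Gaussian noise has SD 0.01 DN. The terrain is a smooth two-sine relief
of 5 cm amplitude; canopy pixels sit `PH` above it with 2 cm elevation
noise, soil pixels on it exactly.

**Design and noise.** The default calibration design is 10 genotypes ×
5 replicates (year 1) + 4 replicates (year 2) = 90 physical plots,
photographed at the nine seasonal flight dates (274–1016 GDD in year 1,
215–1130 in year 2), giving 410 plot-observations. Genotype effects are
multiplicative log-normal (SD 0.15) on the asymptote; late-maturity
genotypes get ×1.2 asymptote and +40 GDD inflection, so they accumulate
more biomass over a longer season. Measured FB adds Gaussian noise of SD
0.15 kg/m² (~5% of the asymptote) to the latent plot biomass; plot
height adds SD 0.02 m. No per-plot variance components are published for
trials of this kind at this scale, so these SDs are free choices fixed
once at breeding-trial-realistic values. The expected MAE of a *perfect*
model is therefore `0.15·√(2/π) ≈ 0.120 kg/m²` — the noise floor quoted
by the evaluation.

Everything — genotype effects, pixel fields, split assignments,
bootstraps — derives from one integer seed; a fixed seed reproduces the
trial bit-for-bit.

## Trait extraction

Regions of interest are axis-aligned rectangles (0-based, half-open).
Soil masking classifies a pixel as plant when NDVI = (NIR−R)/(NIR+R)
exceeds a threshold (default 0.4; an excess-green rule 2G−R−B > t is
available). Pixels with NIR+R = 0 are soil. Canopy cover is the
percentage of plant pixels in the ROI; mean digital numbers and plant
height are averaged over **plant pixels only** — soil pixels have
DSM ≈ DTM and would bias height toward zero. Negative per-pixel DSM−DTM
values (elevation noise) are clamped to 0 before averaging, since
heights are physical. An ROI with no plant pixel yields NaN traits that
propagate as missing predictors, never as zeros.

## Vegetation indices

The panel is a YAML registry of 31 five-band indices computed on the
plot-mean DNs (indices-on-means, matching the order of operations in the
manual workflow, not means-of-per-pixel-indices). The four named
headline indices use their canonical literature forms:

    TGI  = −0.5·[190·(R−G) − 120·(R−B)]
    GCI  = NIR/G − 1
    CIVE = 0.441·R − 0.811·G + 0.385·B + 18.78745
    GNDVI = (NIR−G)/(NIR+G)

The remaining 27 are standard NIR/red-edge/visible indices (NDVI, NDRE,
SAVI, EVI2, MSAVI, OSAVI, RDVI, SR, DVI, ExG, ExR, ExGR, VARI, MGRVI,
NGRDI, RGBVI, GLI, MTCI, NDWI, WDRVI, NLI, MNLI, SIPI, PSRI, ARVI, RECI,
GDVI). The registry is data, not code: a user with a different panel
swaps the YAML. Formulas are parsed once through a restricted `ast`
whitelist (+ − × / ^, parentheses, band symbols, constants); a zero
denominator or non-finite result yields NaN. Each entry is tagged
`scale_invariant`, and the tag is property-tested (tagged indices are
unchanged under a common positive rescale of all five DNs; affine
indices such as TGI scale linearly).

## Predictor pruning

Pearson correlations are computed pairwise with two-sided t-test
p-values (p-values are reported for display only; elimination uses |r|
exclusively). The mean-absolute-correlation (MAC) filter, default
cutoff 0.8: repeatedly locate the largest-|r| surviving pair above the
cutoff; within it remove the variable with the larger MAC against the
current survivors; recompute and repeat. This "exact" variant is
order-independent and is verified against an exhaustive independent
re-trace on hundreds of random matrices; a faster single-pass "greedy"
variant is available behind a flag. MAC ties (within 1e−12) drop the
variable later in registry order, and the removal log records every
step. Canopy cover and plant height are never filtered — only the index
panel. A certified post-condition asserts on every run that no surviving
pair exceeds the cutoff.

On generator data the 31-index panel collapses to 3–5 survivors beyond
CC/PH (the exact set is data-dependent, as it is in any real trial). The
qualitative 31 → 2 reduction is demonstrated on a planted panel: 29
noisy affine copies of two latent factors plus the two clean factors,
constructed so every copy exceeds the cutoff with its factor but always
carries the larger MAC; elimination then removes all 29 copies and
retains exactly the clean pair.

## Regression models and evaluation

The random forest uses canonical regression-forest settings — 500 trees,
3 candidate predictors per split, variance-reduction splitting, no depth
limit, bootstrap resampling — via scikit-learn. PLSR standardizes
predictors and chooses the latent-variable count (up to 10) minimising
RMSE in an inner 5-fold CV on the training partition.

Evaluation is leave-group-out cross-validation: 10 repeats of a uniform
random 70/30 plot-level split (no stratification; stratified-by-GDD
splitting is available), metrics computed on each held-out set and
averaged over repeats (pooled-prediction metrics are also reported;
averaged-per-repeat is primary).

**R² is the squared Pearson correlation** between actual and predicted —
not 1 − SSE/SST. The two diverge for biased predictions: this R² lies in
[0, 1] and is invariant to affine transforms of the predictions, so MAE
and RMSE (which retain bias) must be read alongside it. MAE ≤ RMSE holds
per repeat (Jensen), with equality iff all |residuals| are equal.

Importance is reported on a relative 0–100 scale: permutation importance
for the forest (mean squared-error increase when one predictor is
shuffled; 5 seeded repeats on the training table) and absolute
standardized coefficients for PLSR. Only the maximum is pinned to 100;
the minimum is not forced to 0, preserving ratios. Residual spread is
summarised as the SD of pooled (actual − predicted) residuals with a
seeded 2000-resample percentile-bootstrap 95% interval.

On the default calibration table the forest reaches averaged R² ≈ 0.98
and MAE ≈ 0.13 kg/m² — close to the 0.120 kg/m² noise floor — slightly
ahead of PLSR, with plant height the dominant predictor; a
response-permuted null collapses to R² ≈ 0.01. These are
parameter-recovery results on synthetic data: they demonstrate that the
pipeline recovers a planted signal at the planted noise level, not that
any particular accuracy would be achieved on real imagery, where
lodging, weeds, shadows and radiometric drift add error sources the
generator deliberately omits.

## Temporal screening

Trials are labelled ED/LD (early/late maturity under drought) and EC/LC
(controls). Predictions are clamped at 0 (count logged). Group summaries
per trial × GDD × year report the median, linear-interpolation quartiles
(the outlier fences depend on the quartile convention, so it is fixed,
not configurable), IQR-rule outliers (beyond Q1−1.5·IQR or Q3+1.5·IQR)
and a seeded percentile-bootstrap 95% CI of the median (2000 resamples —
the CI construction for such boxplots is rarely stated, so the bootstrap
choice is documented here). Drought contrasts are control − drought
median differences per stratum with bootstrap CIs; strata missing an arm
are skipped with a warning. Flights are aligned across years by nominal
GDD bins (230/390/706/917 by default, half-width ±25 GDD).

With the default screening panel (32 early + 32 late genotypes, both
environments, two years) the contrast is statistically indistinguishable
from 0 at 230 GDD and ≈ 1.8–2.0 kg/m² with CIs far from 0 at 917 GDD,
and late-maturity medians exceed early ones at the final flight — the
planted drought biology propagated through the fitted model. Note the
per-stratum early-season check is a null hypothesis: any single 95% CI
excludes zero ~5% of the time by chance, which is why the pooled
earliest-GDD contrast is the robust headline number.

## Pipeline and reproducibility

`run_pipeline` executes simulate → extract → indices → filter → train →
screen from a validated YAML config, deriving one sub-seed per stage
from the master seed (SHA-256 of the stage name folded into a
SeedSequence), and writes a manifest recording stage, seed, wall time
and SHA-256 of every output file, so each number is traceable to
(config, seed). Identical configs and seeds give identical output
hashes.

## Known limitations

- No photogrammetric reconstruction: rasters are born co-registered;
  structure-from-motion artefacts, orthomosaic seams and georeferencing
  error are out of scope.
- No lodging, weeds, shadows or within-plot growth gradients — the
  principal real-world error sources for height- and cover-based
  prediction are deliberately not modelled.
- The i.i.d. plant-pixel field understates spatial autocorrelation;
  the clustered mode is a coarse stand-in for row structure.
- The 31-index registry is a canonical stand-in panel; only the four
  named indices are anchored to specific published forms.
- Random-forest predictions cannot extrapolate beyond the calibration
  response range; screening genotypes far outside it would saturate.
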