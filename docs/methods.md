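# Methods

This note documents the models, defaults and design decisions in
`srisoscape`, in workflow order. Section headings match the modules.

## 1. Bedrock model (`bedrock`)

**Ingrowth equation.** ⁸⁷Rb decays to ⁸⁷Sr, so a rock's present-day
ratio is

    ratio(t) = initial + (⁸⁷Rb/⁸⁶Sr) · (e^{λt} − 1)

with t the rock age and λ = ln 2 / t½. The default half-life is
48.8 Gyr (λ ≈ 1.4204 × 10⁻¹¹ /yr). `present_day_ratio` evaluates this
with `expm1` for accuracy at small λt; the test suite checks it against
a 50-digit arbitrary-precision oracle at 10⁻¹² absolute tolerance.

**Rb/Sr conversion.** Laboratories report weight ratios; the equation
needs the atom ratio. Default is the composition-dependent conversion
`⁸⁷Rb/⁸⁶Sr = (Rb/Sr)wt · (2.6939 + 0.2832 · ratio)`; a fixed factor of
2.8936 is available with `mode="fixed"`.

**Lithology distributions.** Each lithology class (GLiM-style codes:
`sc` carbonate, `ss` siliciclastic, `sm` mixed sediment, `su`
unconsolidated, `pa`/`pb` acid/basic plutonic, `va`/`vb` acid/basic
volcanic, `mt` metamorphic) carries a lognormal Rb/Sr (median, log-SD)
and a normal initial ratio (mean, SD, clipped to [0.699, 0.720]).
Carbonates have low Rb/Sr and barely ingrow; acid plutonics ingrow
strongly. `unit_quantiles` Monte-Carlos (default 1000 draws) over the
joint distribution of Rb/Sr, initial ratio and a triangular age
distribution on the unit's (min, mean, max) ages, returning the median
and quartiles. Per-unit seeding (`SeedSequence([seed, unit_id])`) makes
every unit's draws independent of map order. `rasterize_bedrock` writes
the three layers `r.m1` (median), `r.srsrq1`, `r.srsrq3`.

## 2. Grids and projection (`grids`, `projection`)

Rasters are ESRI ASCII grids (`.asc`, NODATA −9999) with a JSON sidecar
for the stack manifest. The pixel model: top-left origin, row-major,
half-open pixel bounds, values at cell centres, floor indexing; missing
data is NaN. Resampling is bilinear for continuous layers and
nearest-neighbour for categorical ones (bilinear on a categorical layer
is an error; auto mode picks by kind). A cylindrical equal-area
projection (`"cea:<lon0>:<lat_ts>"`, spherical radius 6 371 007.2 m)
provides metric coordinates without a GDAL/PROJ dependency; `"wgs84"`
passes longitude/latitude through. Log transforms are supported as
stack transform tags and refuse non-positive inputs with a count.

## 3. Samples (`samples`)

Sample records carry `site_id, longitude, latitude, substrate, ratio,
source`. Substrate `excluded` rows are dropped from all statistics.
Sites aggregate to the **median** ratio across retained records.
Covariates are read from the pixel containing the projected site
(cell-centre value, half-open bounds); sites outside the stack or
hitting missing data are dropped and counted.

## 4. Regression engine (`regression`)

**Learners.** Registry names: `rf` (random forest, 500 trees;
`max_features` resolved from {⌈p/3⌉, ⌈√p⌉, p} by out-of-bag RMSE
computed inside the training data, or fixed explicitly), `glm`
(one-hot categoricals with drop-first encoding, recursive VIF > 10
elimination, OLS), `ok` (ordinary kriging, below), `mean`
(intercept-only). New learners register via `register_learner`.

**Cross-validation.** Repeated k-fold, default 10 folds × 5 repeats.
Fold assignments are a pure function of (seed, repeat, n), so two
learners evaluated under the same scheme share folds exactly — the
prerequisite for the paired Wilcoxon signed-rank comparison
(`compare_models`; exact null for ≤ 25 pairs, normal approximation with
continuity correction above). Per-fold metrics: RMSE and R² (squared
Pearson correlation by default; `kind="ss"` gives 1 − SSE/SST).

**Variable selection.** Two stages: (1) screening — append a pure-noise
probe covariate, fit several seeded forests, discard covariates whose
mean permutation importance does not exceed the probe's maximum
(a data-driven noise threshold); (2) forward CV — add survivors in
importance order, keeping each only if it improves mean CV RMSE by more
than 1% relative. Selection optimizes prediction error only; run the
residual correlogram afterwards — a dropped smooth covariate shows up
there (see `examples/04`).

## 5. Ordinary kriging (`kriging`)

Empirical semivariogram: ½ mean squared difference per distance bin
(15 bins to half the maximum pairwise distance by default). Model
fitting: spherical, exponential and Gaussian families by pair-count-
weighted least squares from 8 seeded multi-starts; lowest weighted SSE
wins. Prediction solves the bordered ordinary-kriging system (weights
sum to 1 via a Lagrange multiplier); duplicate coordinates are averaged
first; a singular system falls back to the global mean with a flag.

**Numerical nugget.** A Gaussian variogram with a near-zero nugget
produces a system with condition numbers up to ~10¹⁸ whose "solutions"
carry huge oscillating weights. If the system's condition number
exceeds 10¹⁰, `krige` adds the smallest numerical nugget from
(10⁻⁸, 10⁻⁶, 10⁻⁴) × sill that brings it under, and warns. Zero jitter
is tried first, so exact interpolation with well-conditioned zero-nugget
models is unaffected.

## 6. Quantile regression forest (`qrf`)

Meinshausen's estimator: each tree stores the in-bag training responses
per leaf; a query row receives weight 1/(leaf size) for every in-bag
response in its leaf, averaged over trees; conditional quantiles are
read from the weighted empirical response distribution via the
left-continuous generalized inverse (the predicted quantile is always
an actual training response). Trees are grown on explicit bootstrap
resamples so in-bag bookkeeping is owned locally; out-of-bag rows get
zero weight.

**Leaf size.** Quantile trees use `min_samples_leaf=10` (the R
quantregForest `nodesize` default), not fully-grown trees: with 1-row
leaves the per-tree conditional distributions collapse onto too few
responses and the intervals undercover (observed: 95% intervals
covering ~76% with leaf size 1 vs ~92–93% with leaf size 10 on the
standard benchmark). The point forest is unaffected.

**Calibration audit.** `coverage` reports the fraction of held-out
observations inside the central interval. The acceptance benchmark uses
5-fold cross-validated coverage (every site held out exactly once) so
the estimate uses all sites rather than a noisy single split.

## 7. Diagnostics (`diagnostics`)

**Moran correlograms.** Per distance class, binary weights select site
pairs in the class; p-values come from seeded random relabelings
(default 999, +1 finite-sample correction), shared across classes.
Classes with < 30 pairs are flagged low-power. The `alternative`
parameter defaults to `"two-sided"`; residual-whiteness audits use
`"greater"` (is unmodelled *positive* structure present?) because any
cross-validated or bagged smoother leaves a small negative short-range
artifact — residuals in a covariate neighbourhood are centred on their
common fit, an O(−1/k) effect that grows with sampling density and is
not evidence of missing covariates. This matches the one-sided
convention of the standard spatial-statistics permutation tests.

**Within-population variability.** Median of per-site sample SDs
(n−1 denominator) over sites with ≥ 2 records — the dataset's noise
floor; no site-level model should be judged below it.

## 8. Isoscape and assignment (`isoscape`)

Applying a model over the stack yields the mean surface; the quantile
forest adds median, 2.5% and 97.5% surfaces, whose difference is the
published uncertainty map. Missing covariate cells stay missing.
Assignment of a measured ratio r with analytical SD σₘ gives each cell
the normal likelihood N(r; mean, √((width/3.92)² + σₘ²)) — 3.92 SDs
span a central 95% normal interval — normalized over non-missing cells
(uniform spatial prior), computed in log space to avoid underflow.
`credible_region` accumulates cells in descending posterior order until
the requested mass is reached.

## 9. Synthetic regions (`synthetic`)

The simulator generates, from one master seed (stage-wise
`SeedSequence` derivation, bit-reproducible): Voronoi geology (units
with lithology drawn from configured frequencies and age from the
class range), one true ingrowth draw per unit (so the bedrock-model
covariates are informative but imperfect), sea-salt deposition decaying
exponentially from the western edge (50 km e-fold) and a south-strong
dust gradient, and a true bioavailable surface by three-endmember
linear mixing (bedrock weight by lithology — carbonates weather fast —
salt at 0.7092, dust at 0.7120).

Samples: 1–3 records per site (P = 0.5/0.3/0.2), a site-level offset
(SD `measurement_sd` = 0.0005) shared by a site's records, plus
per-record substrate scatter. The record SD is calibrated analytically
(χ-distribution mixture median) so the *observable* median within-site
SD equals the configured `substrate_sd` = 0.0003 — the naive choice
would bias the statistic low by ~27% at these record counts.

Known simplifications: linear mixing of ratios without Sr-concentration
weighting; piecewise-constant geology; isotropic noise; no rivers or
soil processes. The simulator is a test bed for the estimators, not a
geological model.

**Standard benchmark.** 200 × 200 grid of 1 km cells, 25 units, 1500
sites, master seed 42. On it: rf mean CV RMSE ≈ 0.0007 vs ok ≈ 0.007
and glm ≈ 0.010 (paired Wilcoxon p < 10⁻⁹ for both), residuals
spatially white (one-sided correlogram, all p > 0.05), 5-fold
cross-validated 95%-interval coverage ≈ 92.7%.

## 10. Pipeline (`pipeline`, `cli`)

`run_pipeline` executes stack → extract → train → predict → diagnose
from a validated YAML config; every artifact is recorded with its
SHA-256 in `report.json`, failures name the stage, and identical
(config, seed) pairs produce identical artifact hashes. The CLI wraps
each stage plus the simulator.
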