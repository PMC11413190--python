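# Methods

This note records the models, conventions, parameter choices and known
limitations of the pipeline, in the order data flow through it.

## Grid and geometry

All rasters live on one regular lon/lat grid with cell-center registration
(default resolution 0.08°). Depths are metres, positive down, everywhere —
bathymetry and depth-level centers alike — to avoid the classic
elevation/depth sign bug. Land is encoded as missing values, never as depth
zero: zero-depth ocean cells are legal. Per-cell areas use the spherical
band formula A = R²·Δλ·(sin φ₂ − sin φ₁) with R = 6371 km; across a few
degrees of latitude the correction over a flat approximation is small, but
exactness is free.

Depth levels default to 24 level centers thickening quadratically to
1200 m, the shape reanalysis products use (fine near the surface, coarse at
depth).

## Bathymetric projection

A 4-D variable (lon, lat, depth level, month) is collapsed onto the seafloor
by selecting, per horizontal cell and month, the value at the depth level
coinciding with the seabed. The default policy, **deepest-valid**, takes the
deepest level whose center lies at or above the seabed and whose value is
non-missing; it never fabricates values below the data column. Cells
shallower than the first level center use the first level (surface water is
the best available proxy at zero-depth cells). Columns with no valid level
at or above the seabed fall back to the deepest non-missing level and are
flagged in the output's provenance variables (`level_index`, `fallback`).
An **interpolate** policy linearly blends the two levels bracketing the
seabed when both carry data; whether a projection of this kind should
interpolate between levels or take the nearest one from above is genuinely
open, so both are recorded as switchable policies and the conservative
nearest-from-above is the default. Projection is independent per month and
exactly reproducible by a per-cell column scan (the test suite's oracle).

## Preprocessing

Monthly climatologies are cell-wise, missing-aware means per calendar
month; a calendar month absent from the input is an error naming the month.
Grid standardization is bilinear interpolation at target cell centers, with
missing values propagating whenever a stencil corner is missing.

The collinearity screen computes pairwise Pearson correlations over jointly
non-missing cells of the **annual-mean** layers (filtering once, not per
month; a config switch allows pooled monthly values instead, since which of
the two the original workflow used is not stated). Elimination is greedy
and deterministic: repeatedly drop the variable with the highest mean
absolute correlation to the others until no pair exceeds the threshold
(default 0.70, strict inequality — a pair at exactly 0.70 is retained),
ties broken lexicographically. A layer constant over the joint mask has
undefined correlation and is treated as uncorrelated, with a warning.
Static layers (bathymetry BAT, bottom hardness BH) have no future
counterpart and are injected unchanged into every scenario's stack.

## Future forcing

**Delta-method bias correction.** With observed climatology O,
historical-model climatology H and future-model field F on the coarse model
grid, the corrected field is F' = F + (O − H). This is the anchored
convention: a perfect model (F = H) returns the observation exactly, and the
climate signal is preserved cell-wise (F' − O = F − H). The literal phrase
"the bias O − H was subtracted from the future projections" would give
F − (O − H), which violates the anchoring identity; it is available behind
`convention="literal"` for comparison but is not the default, because the
anchoring identity is the defining property of the method. Bias is computed
and applied per calendar month. Corrected fields from multiple climate
models are combined by a cell-wise missing-aware mean.

**Downscaling.** The downscaler predicts fine-grid values from the
bilinearly interpolated coarse value plus local covariates (lon, lat,
bathymetry); these are the standard minimal set and all available
in-pipeline. The default architecture is **anchored-residual**
(bias-corrected spatial disaggregation): prediction = interpolated coarse
value + f(lon, lat, BAT), with f fitted to the fine-minus-interpolated
residual. The anchoring matters: a free regression on all features need not
carry a unit coefficient on the coarse value — when static covariates
explain most of the training field the coarse coefficient is unidentified —
and then an additive signal imposed on the coarse field (the very thing a
scenario is) arrives damped at the fine grid. The anchored form passes
additive signals through exactly; the free regression remains available
(`anchor=False`). Candidate families for f: robust linear regression
(Huber), a piecewise-linear spline regressor with MARS-like inductive
shape, random forest, a smooth cubic-spline ridge regressor with GAM-like
shape, and a multilayer perceptron. Spline bases extrapolate linearly, not
by clamping, because future inputs deliberately sit outside the training
range. The family with minimal RMSE on a held-out 25% of cells is selected;
ties fall to configuration order. Fits are per variable per month (pooling
is not used; whether the original workflow pooled is unstated).

## SDM ensemble

Pseudoabsences are drawn uniformly from ocean cells not containing a
presence, without replacement within a set; each of the 3 sets matches the
presence count exactly, and depths are filled from the bathymetry layer.
Uniform background sampling is the minimal-assumption choice where no
sampling scheme is prescribed.

The classifier is a random forest with 1000 trees, 8 candidate predictors
per split (clamped, with a warning, when fewer predictors exist — the
default synthetic stack has 6), and minimum node size 5. The ensemble is
structured as 10 repeats × 3 pseudoabsence sets = 30 members, honoring both
the 30 total runs and the 3 sets; each member trains on a 75/25 split
stratified by label (stratification prevents single-class partitions at
small n) and is scored on its held-out 25% at a probability cut of 0.5.
The evaluation cut is deliberately separate from the 0.75 mapping
threshold; 0.5 is the deterministic default and both are configurable.
Skill is summarized as mean ± 2 standard deviations over members. One
sensitivity/specificity pair is reported per member alongside TSS, κ and
accuracy; per-metric "sensitivities" (a TSS-sensitivity and the like) have
no standard definition and are not attempted.

Training uses the annual-mean predictor stack; prediction runs per month —
the monthly maps inherit seasonal structure from the predictors, not from
monthly re-training. The ensemble CP(o) is the cell-wise mean of member
probabilities; BP(o) thresholds it at 0.75 (≥ rule at the boundary). A map
that is entirely below threshold in some scenario-month is a legitimate
blank, not an error, and propagates as a blank attribute row.

The classifier backend is pluggable (any sklearn classifier with
`predict_proba` can stand in); the random forest is the reference
implementation and maximum-entropy models are out of scope.

## Spatiotemporal attributes

- **Area**: sum of spherical cell areas over presence cells; empty maps give
  0 km².
- **Depth range**: min/max/mean bathymetry over presence cells; undefined
  (NaN, with a warning) for empty maps.
- **Aggregation index**: AI = 100·e/max_e, where e counts edge-sharing
  (rook) like-adjacencies among presence cells, each shared edge once, and
  max_e is the largest-integer-square maximum — with m = ⌊√n⌋ and
  r = n − m²: max_e = 2m(m−1) if r = 0, 2m(m−1)+2r−1 if 0 < r ≤ m, else
  2m(m−1)+2r−2. AI is undefined for n ≤ 1 (reported missing, with a
  warning). The implementation is verified exhaustively against a pairwise
  adjacency oracle on all 4×4 maps with 2–9 presence cells.
- **Suitability change**: Δ = future CP(o) − current CP(o) per cell,
  classified positive above +0.10, negative below −0.10, else no-change.
  The band is read as an absolute change of 0.10 on the [0, 1] scale (ten
  percentage points), because a relative 10% explodes at near-zero
  suitabilities; the relative reading sits behind `mode="relative"`.
  Percentages are computed over the union of the current and future
  presence footprints (the evaluation domain is otherwise unspecified, and
  the union matches how change maps are drawn inside/outside the current
  range polygon).
- **Gain/loss**: gained = 0→1 transitions, lost = 1→0, with areas from the
  same spherical formula; gained − lost = future area − current area holds
  exactly, by construction.
- **Seasonality**: Kendall τ-b between the current and a future scenario's
  12-month series of an attribute, exact p-value for untied n = 12
  (normal approximation with tie correction otherwise); a departure is
  flagged when p ≥ 0.05. Taken literally this rule classifies a
  *significantly negative* τ — an inverted seasonality — as "no departure";
  the rule is implemented as written and this quirk is deliberately left
  visible. Months with no predicted distribution contribute 0 to the series
  (zero area is meaningful; the test needs length-12 pairs). Constant
  series leave τ undefined and count as departures, with a warning.

Attribute tables carry one row per species × scenario × month, with
increase/stable/decrease flags against the current decade (relative change
beyond ±1%) and the suitability-change percentages. Gain/loss is computed
from the binary maps; the alternative continuous-CP(o) reading of "gained
areas" is not implemented.

## Synthetic data: what it emulates, and what it does not

The generator is the study design, not a dial; its defaults were fixed
while designing the experiments and define the conditions under which the
test suite's statements hold.

- **Bathymetry**: a coastline along one grid edge, monotone deepening
  offshore to 1200 m (exponent 1.6), seeded noise (sd 25 m), land as NaN.
- **Environmental cubes**: value = spatial field + vertical profile +
  seasonal cycle + noise. Vertical profiles are exponential approaches to a
  deep value (thermocline/halocline shape, e.g. bottom temperature
  28 → 4 °C with a 60 m e-folding scale) rather than linear in depth — a
  linear profile would make every bottom-projected field a near-perfect
  linear alias of bathymetry, where real retained predictors are pairwise
  |r| ≤ 0.70. Spatial fields are smooth seeded random fields (unit
  variance, mesoscale correlation length), one per variable. Seasonal
  cycles are sums of wrapped Gaussian bumps (σ = 1.2 months) at declared
  peak months, monomodal or bimodal, cyclic over the year.
- **Candidate collinearity**: one derived layer (a productivity-like
  composite of precipitation and a second driver, correlated with
  precipitation above the 0.70 screen) is included so the filter's
  elimination step runs in every pipeline execution.
- **Future fields**: block means of the current field on a coarse grid
  (factor 10–12, ≈1° from 0.08°), plus a known additive model bias, plus a
  known additive climate delta scaled linearly by pathway intensity
  (ssp/8.5) and decade (2030: 0.5, 2050: 1.0). Defaults at SSP 8.5/2050:
  +2 °C bottom temperature, −1 PSU bottom salinity, +0.1 m SSH, −50 mm
  precipitation. Non-divisible coarse factors truncate trailing cells with
  a warning.
- **Species**: steep logistic niches (tolerance envelopes nearly binary) on
  one or two predictors, occupying roughly 10–30% of the domain — matching
  the range-to-domain ratios of the real species this stands in for — with
  occurrence counts 2381 / 237 / 288 / 432 / 94 as compiled for the five
  shrimp species. Presences are drawn with probability proportional to the
  true suitability, with depths read from the bathymetry.

What the generator does **not** emulate: real circulation (currents,
upwelling, the ITCZ), spatial sampling bias in occurrence records,
inter-annual variability beyond i.i.d. noise around the climatology,
non-additive climate change (variance or seasonality shifts), and curvilinear
model grids. Passing tests therefore demonstrate that the pipeline's
machinery recovers known structure under clean conditions; they do not
certify skill on real data, where pseudoabsence contamination, sampling
bias and commission error can inflate apparent performance.

## Validation experiments and problem sizes

The self-checks in `benthoshift.validation` run on the default 50 × 60-cell
grid:

- **Range recovery**: 500 presences from a steep logistic niche on a planted
  smooth predictor (independent of bathymetry, alongside two noise layers
  and BAT); the 30-member ensemble's binary range at 0.75 is compared with
  the true range by Jaccard overlap, and the planted predictor's importance
  share must be maximal. The planted field is mean-centered so the niche
  fraction is stable across seeds; with a niche at ~20% of the domain,
  pseudoabsence contamination leaves ensemble CP(o) comfortably above the
  0.75 cut inside the niche.
- **Delta recovery**: a monthly field with mesoscale structure (resolved by
  the coarse grid, identifying the coarse predictor), weak covariate-linked
  components and cell noise (sd 0.3) is climatologized over 4 years,
  aggregated to a biased coarse "model", shifted by a known +2, corrected,
  and downscaled; the mean absolute error of the recovered change against
  +2 must sit below the generation noise sd.

The demo configuration scales the reference setup down (two species, 250/200
presences, 100-tree forests, 2 repeats, linear + spline downscalers) so a
complete double run finishes in about a minute; the reference configuration
(five species, full occurrence counts, 1000 trees, 30 members) is the
default for `benthoshift run`.

## Numerical and policy details

- All generators and fits are pure functions of (configuration, seed);
  stage seeds derive from the run seed by hashing stable stage tags, and
  tables are written with fixed float formatting, so identical runs are
  byte-identical.
- NetCDF I/O uses the classic (NetCDF3) format; 64-bit integers and
  booleans are downcast on write.
- Quarterly aggregation (mean of monthly CP(o) within quarters) is a
  reporting convenience only; all computation is monthly.
- The historical-model baseline period and the observed climatology period
  differ in the emulated setup (a shorter model baseline vs. the full
  observed record); the mismatch is reproduced as-is in the configuration
  defaults rather than resolved.
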