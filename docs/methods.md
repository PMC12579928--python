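# Methods

## The problem

Long-term trends in local plant species richness (alpha diversity of
vegetation plots) are usually estimated from resurvey time series, which are
geographically sparse, biased toward well-preserved sites, and thin before
the 1990s. Most archived vegetation plots, by contrast, were surveyed exactly
once ("static" data). Because species richness is autocorrelated in space and
time, a flexible regression fitted to static plots can interpolate richness
*along the year axis* at each surveyed site, turning one-time observations
into interpolated time series from which change statistics are computed.

`divtrend` implements that pipeline over a synthetic archive with a fully
known richness surface, so every stage can be checked by parameter recovery.

## The model

Plot-level richness S is modelled with a Random Forest on six predictors:

    S ~ easting + northing + elevation + plot area + year + habitat

Forests are used because the signal is strongly non-additive: the power-law
species–area relationship (S = c·A^z) interacts with habitat, and temporal
trends vary in space. Defaults follow standard practice for this model
family: 1,000 trees (the analysis scripts and tests use 200 — see problem
sizes below), node size 5, mtry 3 over the six predictors. Habitat is one-hot
encoded; mtry is mapped proportionally onto the encoded columns, since the
tuning range 2–6 is defined over the six original predictors. Tuning is a
single 10-fold CV over the 25-point grid node size {2, 5, 10, 15, 20} × mtry
{2, …, 6}, winner = lowest mean RMSE, ties broken toward the smaller node
size and then the smaller mtry (smaller values are the more flexible model;
the tie-break is only there to make the choice deterministic).

Accuracy is reported as RMSE and R², with R² defined as the squared Pearson
correlation between observed and predicted richness. Random (not blocked)
cross-validation is the primary evaluation: the model's job is
interpolation, and blocking on predictors (coordinates, year) removes
exactly the gradients it is supposed to learn. Block CV (contiguous
spatial/temporal blocks as folds) is provided as a stress test of
generalisation to unseen regions or periods.

The fitted ensemble exposes the full per-tree prediction matrix; the
aggregate prediction is the mean over trees. Training rows are put in a
canonical order before fitting so that the fit is invariant to input row
order under a fixed seed.

## Interpolation and change statistics

For every plot sampled in 1960–2020, richness is predicted for each of the
61 years with site covariates fixed and plot area standardized to a
per-habitat policy area. For real European archive data the habitat median
areas are forest 300 m², grassland 20 m², scrub 64 m², wetland 50 m²; on
synthetic data the policy is the per-habitat median of the generated areas.
Change between two years uses predictions at exactly those years (not
period averages):

* percent change: 100·(S_end − S_start)/S_start,
* log response ratio: ln(S_end/S_start),
* raw difference: S_end − S_start,
* slope: OLS of all yearly predictions in the inclusive window on year.

Predictions from a forest trained on richness ≥ 1 are bounded below by the
training minimum, so the percent-change denominator is guarded by an
assertion rather than a pseudo-count. Reported period windows are
1960–1980, 1980–2000, 2000–2020 (21 inclusive years each) and the full
1960–2020 span.

## Group trends and intervals

For a group of plots (habitat, region, or habitat × region), each tree's
predictions are averaged over the group's plots at each year, giving a
(trees × years) matrix of tree means. The confidence interval of the yearly
mean is mean ± 1.96·SD/√T over the T tree means (the n in the formula is
the number of trees — that is the sample the SD is taken over); the
prediction interval is the empirical 0.05–0.95 quantile band of the tree
means. Period slopes are OLS fits of the yearly means on year, in
species/year; division by the 1960 mean is a reporting transform applied
after fitting, never before.

Plot-level percent change is mapped by averaging within 50 km × 50 km grid
cells indexed by floor(coordinate/50 km) per axis (half-open cells); cells
with fewer than five plots are omitted, and cell SD uses the n−1
denominator. For regional reporting the arctic, boreal and
Scandinavian-alpine labels are merged into a single high-latitude unit by
default (configurable merge map).

## Validation protocol

Three static training sets are compared: (A) resurvey series degraded to
one uniformly chosen observation each, (B) one-time plots only, (C) both.
Each is split 80/20 stratified by richness (quantile bins, default 10; the
split falls back to unstratified with a warning when bins cannot be
populated). Scoring criteria: (1) richness of the held-out test split, (2)
richness of the independent non-selected series observations, (3) lnRR of
richness between the first and last observation of each series (ties on
year broken by observation index), compared with the model's predicted lnRR
at those two years. Predicted lnRR uses the series' *observed* plot area
rather than the habitat-median policy, because the comparison target is the
recorded richness at that area. In mode C the selected observation may
itself be a series endpoint; this mirrors the real protocol, where the
training pool legitimately contains one observation per series. A
permutation test (1,000 shuffles of the series pairing) attaches a
significance statement to the criterion-3 correlation. The repeat wrapper
re-draws the within-series selection with seeds derived deterministically
from the master seed.

## The synthetic world

The generator emulates the structure of a continental vegetation-plot
archive: ~10⁴ one-time plots plus ~10³ resurvey series (2–8 observations,
first-to-last spans drawn to a median of ≈15 years), sampled 1945–2023 on a
1,000 × 1,000 km plane with coordinate uncertainty < 1 km and
habitat-dependent plot areas (log-uniform; 100–1000 m² in forest, 1–100 m²
elsewhere). The expected-richness surface is

    mu = max(1, [c_h + g_N·northing + g_E·elevation + trend_h(year)·m(northing)] · (A/A_ref)^z_h)

with habitat baselines c_h (forest 16, grassland 30, scrub 20, wetland 12
species at A_ref = 100 m²), a weak poleward decline (−0.005 species/km), an
elevational decline (−2 species/km), SAR exponents z_h of 0.20–0.25, and a
piecewise-linear trend with per-habitat slopes (species/decade at A_ref) of
−1.5…−0.8 in 1960–1980, 0 in 1980–2000, and +0.8…+1.5 in 2000–2020 —
decline then recovery, with the strongest decline in forests and the
strongest recent gain in wetlands. The trend term is scaled linearly from
0.5× at the southern edge to 1.5× at the northern edge (`trend_northing_
modulation = 0.5`), so true plot-level change varies continuously in space
and plot-level recovery is a meaningful target rather than a four-point
comparison. Elevation is a smooth function of the coordinates plus noise,
making it deliberately collinear with space. Observed richness is Poisson
around mu (negative binomial optional, since the archive's true dispersion
is unknown), clipped below at 1 because a vegetation plot contains at least
one vascular plant; for the default baselines the clipping bias is
negligible (< 0.05 species except at the smallest wetland plots).

What the generator does **not** emulate: species-level composition and
turnover, preferential/clustered sampling, habitat misclassification, plot
relocation error, and the real geography of Europe. Passing recovery tests
therefore show that the pipeline estimates what it claims under its own
assumptions — not that those assumptions hold for any particular archive.

Region labels tile the plane into seven blocks arranged in three
latitudinal bands, so the high-latitude merge rule has real work to do.
Optional "contaminant" records violating each filter rule are generated
only on request, to exercise the filter accounting.

## Numerical choices

* Filters are applied in a fixed order (completeness, uncertainty, habitat,
  area, year, extra hooks); each rejected record is charged to the first
  failing rule so the log sums to the rejection count. Filtering is
  idempotent.
* H² statistics are computed from mean-centered partial dependence
  evaluated at the background sample's own feature values; a constant joint
  PD reports H² = 0 with a warning; values are clipped to [0, 1].
* The correlogram is a binned Moran-type estimator (mean of centered
  residual cross-products per distance bin, scaled by the residual
  variance) with a shuffle-based 95% null envelope; empty bins are reported
  as undefined, never imputed.
* Degenerate inputs raise: single-tree interval requests, empty groups,
  non-positive richness in ratio metrics, unseen habitat levels at
  prediction time (no silent extrapolation).
* All randomness flows through explicit integer seeds; generation, fitting,
  interpolation and validation are byte-identical across runs with the same
  master seed.

## Problem sizes

The analysis scripts and the acceptance script run the full pipeline at
20,000 static plots, 1,000 series and 200 trees, with interpolation and
trend aggregation on samples of 1,000–8,000 plots and tuning/repeated-CV at
reduced scale (3,000–4,000 rows, 50 trees); these sizes give stable
recovery statistics while keeping a single run in the tens of seconds. The
unit-test world uses 2,500 plots and 60 trees.

## Known limitations

* The method interpolates along time at surveyed sites only; it is not a
  spatial extrapolator, and the validation of the one-time-plots-only mode
  (B) shows why: its change predictions at series sites are clearly worse
  than those of modes that saw those sites' own data.
* Trend estimates at individual plots are noisy; the method's strength is
  group-level averages, where tree-level and plot-level noise cancel.
* The interval construction captures ensemble spread, not full predictive
  uncertainty; it has no coverage guarantee.
* A forest cannot predict outside its training richness range, which
  compresses extreme changes (conservative bias).
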