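# Methods

## Scope and model

The package estimates a continuous δ³⁴S surface ("isoscape") over a
landscape from point measurements of bone-collagen sulfur, and uses that
surface plus its uncertainty to infer where individuals lived. The
modelling chain is: collagen quality screening → covariate extraction at
site coordinates → random-forest regression of δ³⁴S on 21 environmental
covariates → quantile-based uncertainty surface → per-individual posterior
origin maps → rule-based non-local flagging. All components assume δ³⁴S
varies with environment (sea-spray deposition decaying with distance from
the coast, elevation, gravity/lithology proxies, soils) but is measured on
individuals with substantial extra-environmental noise (diet averaging,
bone turnover, analytical error), summarised as a single within-site SD.

## Collagen quality screening

Atomic ratios from elemental weight percentages use fixed atomic weights
C = 12.011, N = 14.007, S = 32.06:

    C:N = (%C/%N)·(14.007/12.011)
    C:S = (%C/%S)·(32.06/12.011)
    N:S = (%N/%S)·(32.06/14.007)

Retention windows: %Col ≥ 1, %C ∈ [30, 44], %N ∈ [11, 16],
%S ∈ [0.15, 0.35], C:N ∈ [2.9, 3.6], C:S ∈ [300, 900] (600 ± 300),
N:S ∈ [100, 300] (200 ± 100). All bounds are treated as closed intervals:
a value exactly on a bound passes. Laboratory-reported ratios, when
present, take precedence over recomputed ones. A missing metric never
vetoes retention (diagenesis cannot be diagnosed from an absent number);
for isoscape use, three extra rules apply — published non-locals are
dropped (they carry a foreign signal), records with only a δ³⁴S value are
dropped, and samples with no sulfur-bearing QC information at all
(%S, C:S, N:S all absent) are dropped, because the response being modelled
is exactly the quantity whose preservation cannot then be checked.
Screening is a pure partition (retained ∪ excluded = input) with
machine-readable per-sample reasons, and is idempotent.

## Geographic primitives

Rasters are 2-D grids with an upper-left origin, stored as plain-text
ESRI ASCII grids. Two coordinate regimes: geographic WGS84 (cell size in
degrees, distances by haversine on a 6371-km sphere) and planar
kilometre grids (used by the synthetic world; Euclidean distances).
Cells are half-open with edge points belonging to the north-west cell.
Resampling onto a common grid is bilinear for continuous layers and
nearest-neighbour for the age/categorical layers; nodata propagates.

Distance to coast: each land cell holds the distance to the nearest
sea-cell centre (sea = valid cells at or below sea level); on planar grids
this is computed with an exact Euclidean distance transform, on degree
grids by direct haversine minimisation. A site is **coastal** iff its
distance to the coast is below 30 km *and* no cell on the straight
transect to its nearest sea cell (supercover traversal, endpoints
included; corner hits include both adjacent cells) reaches 500 m
elevation; otherwise **inland**. Ties in the nearest-sea-cell search break
in row-major order.

## The isoscape forest

`IsoscapeForest` wraps a scikit-learn regression forest (defaults:
1000 trees for production fits, mtry = ⌊p/3⌋, minimum leaf size 5 — the
regression-forest conventions) and additionally retains, per tree, the
bootstrap multiplicity of every training row and its leaf assignment.
That bookkeeping supplies:

* **Out-of-bag predictions** — each row predicted by the trees whose
  bootstrap sample omitted it.
* **Permutation importance (%IncMSE)** — per tree,
  100·(MSE_perm − MSE_oob)/MSE_oob on the OOB rows with one variable
  permuted, averaged over trees; the classical SD-normalised variant and
  the raw mean decrease are options.
* **Node-purity importance (IncNodePurity)** — the decrease in weighted
  node sum-of-squares attributable to splits on each variable, summed per
  tree and averaged over trees.
* **Response quantiles** — for a prediction point, the in-leaf training
  responses of all trees are pooled with their bootstrap multiplicities
  and empirical quantiles are read off that multiset (linear
  interpolation, matching `np.quantile` on the expanded pool). The
  17th/83rd pair gives the pseudo standard deviation
  `pseudo_sd = (q83 − q17)/2`, which equals ~0.95 SD for a normal
  distribution. These are *response-level* quantiles: they include the
  within-individual noise present in the training responses, not only the
  uncertainty of the mean.

**Cross-validation** is repeated k-fold (defaults k = 10, 5 repeats)
*grouped by site*: all individuals of a site share a fold, because
individuals at one site share one covariate vector and ungrouped folds
would leak that vector into training. Out-of-fold predictions are pooled
within a repeat; RMSE and R² are averaged over repeats. An alternative
`train_fraction` mode runs repeated grouped shuffle splits (e.g. 80/20)
instead. All fold draws derive from one seed; identical inputs and
configuration reproduce identical numbers bit for bit.

**Model fit report**: per-site mean observed vs mean OOB-predicted δ³⁴S;
a site is flagged when its mean residual falls outside the central 95%
(2.5th–97.5th percentiles) of the per-row OOB residual distribution.

## Three-step variable selection

The selector mirrors the threshold / interpretation / prediction scheme of
VSURF-style selection:

1. **Thresholding.** Raw permutation importances are averaged over several
   seeded forests (default 8 forests); variables are ranked by mean
   importance. A CART regression tree fit to the rank-ordered importance
   *standard deviations* supplies a data-driven threshold (its minimal
   prediction); variables at or below the threshold, or with non-positive
   mean importance, are dropped. If nothing survives, the top-ranked
   variable is returned with a warning.
2. **Interpretation.** Nested models over the ranked survivors are scored
   by OOB MSE (averaged over a few replicate forests); the model with
   minimal error wins, ties favouring fewer variables.
3. **Prediction.** Variables are re-added stepwise and kept only if they
   lower OOB error by more than the **noise jump** — the mean absolute
   error change observed when adding known-uninformative variables. The
   reference set for that jump is the top-ranked variables *eliminated at
   step 1* (appended one by one to the full step-1 model); when step 1
   eliminated nothing, the flat tail of the step-2 error sequence is used.
   All nested models in steps 2–3 are evaluated with the *same* replicate
   seeds, so successive differences are paired comparisons and
   forest-construction randomness largely cancels out of the jumps.

Step sizes (8 threshold forests, 3 replicate fits, 100 trees) are the
package's working defaults for the ~400-row regimes it targets; they trade
a little statistical polish for runs measured in seconds.

## Geographic assignment and non-local flagging

For an observed value `y` and surface cells with mean `μ_c` and spread
`s_c = sqrt(pseudo_sd_c² + sd_individual²)`, the posterior is the
normalised normal likelihood `N(y; μ_c, s_c)` over valid land cells
(uniform spatial prior; sea/nodata cells keep zero mass but stay in the
raster). `sd_individual` defaults to 0: because the pooled-leaf quantiles
are response-level, `pseudo_sd` already contains the within-individual
spread, and adding a CV-RMSE-sized term again would double-count it —
in development runs that inflated 80% credible-region coverage to ~91%.
The parameter remains exposed for analysts whose individual-level spread
(e.g. multi-measurement averaging) differs from the training population's.
Cells with zero total SD behave as point masses: full weight on an exact
match, zero otherwise.

Credible regions take cells in descending posterior order (row-major on
ties) until the requested mass is reached. Coverage of the 80% region,
measured over synthetic individuals with known origins, runs at ~83–87%:
pooled-leaf spreads are mildly conservative where the model interpolates
well — a known trait of quantile-forest intervals — so regions err on the
generous side. One isotope ratio cannot identify a point of origin: all
cells along an isopleth are observationally equivalent, and the posterior
mode is only meaningful in isotope space (its predicted value matches the
individual's origin value), not as a map coordinate.

Non-local flagging is an explicit, logged rule rather than expert
judgement: a sample is non-local iff its δ³⁴S falls outside the closed
Tukey fence `[Q1 − k·IQR, Q3 + k·IQR]` (k = 1.5 by default, quartiles by
linear interpolation) of its baseline group — by default all humans and
animals of the same region class, with at least 4 baseline values. The
fitted fence parameters travel with every output. On cohorts where 10% of
individuals are displaced by ≥ 5 ‰ against a 1 ‰-SD baseline the fence
achieves ≥ 99% sensitivity at < 1% false positives; smaller displacements
are intrinsically confounded with local variation.

## The synthetic world

`make_world`/`sample_world` generate the ground-truth test bed. On an
80 × 120 grid of 2-km cells with sea west of column 25, the true field is

    δ(cell) = β0 + β_spray·exp(−d/λ) − β_elev·elev_km + β_sr·sr + ε(cell)

with defaults β0 = 5 ‰ (inland baseline), β_spray = 10 ‰ at the
waterline, λ = 25 km (the spray term is near zero beyond ~75 km),
β_elev = 2 ‰ per km of elevation, β_sr = 0.5 ‰ per Sr-unit, and smooth
spatial noise ε with 0.5 ‰ SD. These put coastal baselines near 14–15 ‰
and inland baselines near 5–9 ‰ — the magnitude of contrast real
coastal/inland collagen cohorts show. Elevation is a 1500-m ridge parallel
to the coast plus independent along-coast terrain (300 m SD), so elevation
carries signal that distance-to-coast cannot proxy; the Bouguer layer is a
negative affine transform of elevation plus noise (deliberately
redundant, as in real gravimetry); Sr is a patchwise-constant Voronoi
field; the remaining 17 stack layers are pure smooth noise.

Sampling defaults encode the study conditions used throughout validation:
60 sites (40% coastal, stratified by the classification rule), 400
individuals allocated evenly, within-site individual SD σ_within = 1 ‰,
10% migrants whose residence cell lies ≥ 50 km from their burial site, and
10% QC failures created by inflating %S by 2.5× (driving C:S and N:S below
their windows and %S above its own). δ¹³C/δ¹⁵N are group-shifted normals
with a realistic human–animal trophic offset (~4 ‰ in δ¹⁵N) so the cohort
statistics see believable structure.

What the generator does **not** emulate: real geography or geology (no
attempt at actual coastlines or site layouts), dietary marine-resource
signals, temporal trends across periods, covariate measurement error,
spatially correlated *sampling* (sites are uniform over eligible cells),
or non-normal individual noise. Passing tests therefore demonstrate that
the machinery recovers known structure under clean assumptions — not that
real collagen data meet those assumptions.

A separate fixture, `make_recovery_matrix`, serves the variable-selection
recovery experiment: 400 independent rows whose four informative
predictors (named after the geographic drivers) are mutually independent
with peninsular-scale ranges (elevation 0–2500 m, distance 0–150 km,
Bouguer SD 30 mGal, Sr 0–10 units), each contributing ≥ ~1.4 ‰ of
response spread against 1 ‰ noise, plus 17 independent noise columns. In
the spatial world terrain, gravity and coastline are entangled, so "which
variables can be recovered" is only well-posed on this decoupled fixture;
the spatial world instead tests the weaker (and geographically honest)
claim that the distance and elevation analogues survive selection.

## Statistical conventions

* Spearman: average ranks on ties; exact two-sided p by permutation
  enumeration for n ≤ 8 without ties, t-approximation otherwise; the
  method used is reported per call.
* Mann–Whitney: exact p when both groups ≤ 8 and tie-free; otherwise the
  tie-corrected normal approximation *without* continuity correction, so
  identical groups give p = 1 exactly. Null calibration over 1000
  replicates rejects at ≤ 6% for α = 0.05.
* Holm adjustment operates within an explicitly declared comparison
  family (the dict passed to `mwu_holm` *is* the family).
* Fisher's exact test reports the conditional-MLE odds ratio with the
  two-sided hypergeometric p.
* Group summaries never round; presentation rounding is the caller's.

## Numerical choices and degenerate inputs

* Seeds: every stochastic step takes an explicit seed; the package default
  is 20250828. Identical seeds reproduce bit-identical outputs.
* Weighted pooled quantiles replicate `np.quantile`'s linear interpolation
  on the expanded multiset exactly (verified against brute force).
* Constant-response training sets degenerate cleanly: zero CV RMSE,
  all quantiles equal the constant, pseudo_sd = 0 everywhere.
* A row present in every bootstrap sample (no OOB trees) falls back to the
  ensemble prediction in the OOB vector.
* `d34S` outside [−30, 40] ‰ is rejected at load time as implausible for
  collagen; negative percentages are rejected.
* Validation experiments use 100–300 trees and the generator's default
  problem sizes (≈360-row matrices after screening, 7600-cell surfaces,
  1000 assignment draws over four worlds); the full suite runs in about
  three minutes on one CPU.

## Known limitations

* Quantile-forest intervals are conservative in well-sampled regions;
  credible regions over-cover by roughly 3–6 points at the 80% level.
* No spatial autocorrelation modelling (no residual kriging): spatial
  noise uncorrelated with covariates is irreducible here.
* Single-isotope assignment delimits isozones, not points; joint
  multi-isotope assignment is out of scope.
* The Tukey-fence non-local rule is deliberately simple and global per
  group; gradual clines or multi-modal baselines can defeat it.
* The coastal/inland rule uses the current sea mask; shoreline change
  over time is not modelled.
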