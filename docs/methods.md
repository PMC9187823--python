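# Methods

This note documents the models and numerical choices behind `driglucose`:
what is computed, under which assumptions, with which defaults, and what a
passing test does and does not establish.

## 1. Walkable isochrones and ring zones

**Model.** The pedestrian environment is an undirected graph with metric
node coordinates and positive edge lengths. Travel time is network distance
divided by a constant walking speed — no slope, crossing or turn penalties.
Speeds come from an age/sex table with a constant 0.13 km/h male–female gap
and monotone decline with age; the table values themselves are a documented
stand-in (the underlying reference values are not published alongside the
method), bracketing the 4.7 km/h standard-pedestrian speed used for
mapping. Ages below 18 are outside the table's support.

**Origins** are snapped to the nearest edge; origins farther than
`max_snap_m` (default 500 m) raise a flagged snap error rather than being
silently assigned. Reachability is computed with two Dijkstra passes from
the snapped edge's endpoints (no graph mutation); partially reachable edges
are split at the exact cutoff distance, so the reached set is the exact
walkable trace. Equivalence with brute-force shortest-path enumeration is
asserted on small networks.

**Polygonization** buffers the reached street geometry by `buffer_m`
(default 40 m) and dissolves. This is robust on sparse networks where
convex hulls overshoot; the width is a config knob, and a zero buffer is
rejected because the bare 1-D trace has no area. Ten cumulative polygons
(2, 4, …, 20 min) are differenced into disjoint rings.

**Ring mean distance** is defined as walking speed × the time-interval
midpoint (1, 3, …, 19 min → 78.3, 235, …, 1488.3 m at 4.7 km/h). This is a
deliberate modelling decision: it is deterministic, strictly increasing and
independent of network shape, whereas an empirical per-ring average would
make the distance-decay weights fluctuate with street density.

## 2. Exposure profiles

SES values per ring are **area-weighted** means over the census polygons
the ring intersects — the homogeneity assumption (a polygon's attribute
applies uniformly over its area) is inherited from the underlying census
model and is the method's main known bias. Population-share weighting would
need a population raster, which the input contract does not include.

NDVI metrics (median, sample SD, 95th/5th percentiles, linear-interpolation
definition) are computed per ring over cells whose **centres** fall inside
the ring, then distance-weighted like the SES variables — not once over the
whole 20-minute area. A single-cell ring has SD 0 by convention.

**Distance-decay weights** are `w_k ∝ 1 / (1 + exp(b (d_k − m)))`,
normalized to sum 1. Defaults: `b = 0.005` per metre and `m` = half the
outermost ring's mean distance, i.e. unit weight at the home and half
weight mid-way out; `b = 0` degenerates to uniform weights. Both are
exposed in config since the decay shape is a tunable of the method, not a
derived quantity. Missing rings (no census coverage / no valid NDVI cells)
trigger per-variable weight renormalization; a variable missing in every
ring stays missing and is flagged.

## 3. Index model

Variables: 11 SES + 4 NDVI metrics (SES-only and greenspace-only variants
restrict the set). The fit:

1. balance the calibration set: undersample the majority class to 2× the
   minority, then SMOTE the minority to parity (segment interpolation
   between k = 5 nearest minority neighbours). The 1:1 target and 2×
   undersampling factor are package defaults — the source method states the
   combination but not the ratio;
2. PCA on the balanced set's correlation matrix; keep the first
   component's loadings;
3. repeat for `n_iterations` (default 20) independent balanced sets,
   sign-align each loading vector to the first iteration, average, and
   renormalize to unit length. The iteration count and the averaging rule
   are package decisions (the source states only that sets were derived
   iteratively);
4. drop variables with |loading| < 0.05 (config) and refit once — this
   reproduces the documented 15-variables-kept-from-19 style reduction on
   data where some variables carry no signal;
5. orient the sign so the deprivation anchor (government transfer
   payments) increases the score; the greenspace-only variant instead
   orients median NDVI downward;
6. raw score = oriented Σ λ_j z_j with z-scores from the full input data
   (sample SDs, n−1 throughout); rescale linearly to [−1, 1] using the
   min/max raw score over the pooled balanced calibration rows. Scores
   outside the calibration range clamp to ±1 and are flagged rather than
   extrapolated.

Diagnostics (Bartlett sphericity χ² = −(n−1−(2p+5)/6)·ln det R with
df = p(p−1)/2, and KMO MSA from anti-image partial correlations) are
computed on the full input correlation matrix; perfectly collinear inputs
skip diagnostics with a warning since PC1 is still defined. A tied leading
eigenvalue pair raises a degeneracy warning.

The published 15-variable loading table is shipped as constants
(`published_model()`). It carries no standardization or rescale parameters
— those depend on the original cohort — so scoring requires `calibrate()`
on user data first. Its printed loadings are rounded to 2 decimals (their
squares sum to 0.97, not 1), so the unit-norm invariant applies only to
fitted models.

## 4. Risk surface

Cells of a 50-m grid (config) whose centres lie in residential land use
are treated as standard-pedestrian residences; each is snapped, ringed,
profiled and scored. Isochrones are memoized by snapped position (edge +
offset rounded to 1 mm), which makes the surface deterministic and cheap
where cells share a snap. Unsnappable or unprofilable cells become nodata
and are counted in the run report. Conservation (constant inputs →
constant surface) and locality (edits beyond the maximum walking distance
plus buffer cannot change a cell) are asserted in tests.

## 5. Validation harness

Diabetes status: self-report OR medication OR fasting plasma glucose
≥ 7.0 mmol/l (boundary inclusive); all-missing inputs are excluded with a
log entry. Model suites: (a) each predictor alone; (b) index + age, sex,
BMI (or WHR via config), household income as an ordered 1–6 score,
urbanicity; (c) = (b) + smoking, alcohol, diet score, physical activity.
The ordinal income coding is a package decision; the source's coding is
unstated. Fits are maximum-likelihood logistic (statsmodels); separation
and rank deficiency raise errors instead of returning diverged estimates.
2×2 odds ratios use the cross-product with Wald 95% CIs
(`exp(ln OR ± 1.96·SE)`), reproducing all recomputable published intervals
to 2 decimals; zero cells require an explicit Haldane correction.

Performance: stratified 80/20 split (per-class rounded counts), tenfold
stratified CV on the training part, AROC by the rank (Mann–Whitney)
statistic with ties averaged. The classification threshold for
accuracy/sensitivity/specificity is the Youden-optimal cut chosen **on
training data only** (ties → lowest threshold); 0.5 is available
explicitly. J = sensitivity + specificity − 1 holds exactly by
construction.

## 6. Synthetic study areas

The generator states a world loosely matching the motivating setting and
keeps the truth for recovery tests:

- **streets**: jittered lattice (jitter = irregularity × spacing, uniform)
  with up to 25%·irregularity of edges removed, skipping bridges, so the
  graph stays connected;
- **census areas**: Voronoi cells of uniform seed points (mirrored across
  the extent edges for exact clipping); all deprivation-oriented variables
  share one latent Gaussian field with exponential covariance (range
  `ses_spatial_range`) plus independent noise, with marginal means/SDs
  loosely matched to published cohort neighbourhood characteristics and
  loadings echoing documented deprivation-index correlation structure;
  percentages clip to [0, 100] and owned% + rented% = 100 exactly;
- **NDVI**: base 0.34 ± 0.09 × a unit-variance field mixing the polygon
  deprivation surface (weight = `ndvi_ses_coupling`, default −0.4) with
  Gaussian-filtered white noise of kernel scale `ndvi_smoothness`;
- **cohort**: residences sampled on edges (length-weighted) with a 5–25 m
  perpendicular offset; covariate marginals loosely matched to the
  published cohort table; outcome from
  `logit p = α + β·true_index + Σ γ_j·covariate_j` with β = 0.5 by default
  (a moderate, plausible per-SD area effect; the source does not print its
  index OR), the true index being the z-scored latent deprivation of the
  residence's census area, and α calibrated by bisection to the target
  prevalence (default 9.9%, n = 5125 as in the motivating cohort).

What the generator does **not** emulate: realistic street morphology and
OSM semantics, census population heterogeneity within polygons, seasonal
or sensor artefacts in NDVI, spatially structured covariates, or selection
effects in cohort recruitment. A green recovery test therefore establishes
internal consistency of the pipeline under the stated world, not external
validity on real cities; the published headline metrics (75% accuracy,
AROC 0.76/0.78, PCA variance 49.3%, KMO 0.74) depend on the private cohort
and are deliberately not acceptance targets.

## 7. Numerical conventions and degenerate inputs

- Sample (n−1) standard deviations everywhere; constant columns raise a
  named degenerate-variable error.
- Weight vectors renormalize to Σw = 1 within 1e−12 in all paths.
- Raster nodata is NaN in memory, −9999 in ESRI ASCII files.
- Determinism: every stochastic step derives its generator from
  `SeedSequence([master_seed, stage_id])`; identical config + seed gives
  byte-identical outputs, asserted via manifest checksums.
- Time 0 or an empty reached set yields an empty polygon, not an error;
  a zero polygon buffer is an error.
- Known limitations: areal (not population) weighting of census
  attributes; cell-centre raster inclusion (exact area weighting noted as
  an alternative); no CRS reprojection — all inputs must share one metric
  coordinate system.
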