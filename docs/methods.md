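# Methods

This note records the models implemented in `popvuln`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not demonstrate.

## The vulnerability index

For one future scenario, let *s* be the ensemble habitat suitability
(0–1000 integer scale) over the cells of the *present* binary
distribution (the footprint), and let *c* be the survival minimum. The
index is

CCVI(cell) = −(s(cell) − c) / σ,

with σ the sample standard deviation (n − 1 denominator) of the footprint
values. Properties relied on throughout: CCVI = 0 exactly at s = c;
s = c ± σ maps to ∓1; the index is antitone in future suitability; and it
is invariant under any affine rescaling applied consistently to the
suitability values and the center, which is what makes values comparable
across species and modelling scales.

**Center choice.** The survival minimum is described as the minimum
suitable habitat output by the ensemble modelling, so the default centers
at the ensemble binarization threshold (`center_mode="threshold"`). A
generic scaling routine would instead center at the footprint mean; both
modes are exposed (`center_mode="mean"`) because the two disagree whenever
the footprint mean differs from the threshold, and the choice shifts all
CCVI values by a constant (it never reorders populations).

**Aggregation order.** Per-plant extraction (value of the containing
cell, no interpolation) happens before scenario averaging. Averaging is
pointwise-linear, so the order does not change results; extraction-first
matches the per-plant tables the analysis produces. Per-population values
are reported as mean ± sample sd of the plant values; the sd of a
single-plant population is reported as NaN, never 0. Scenario-set means
("2055" = all ten futures; per-pathway = the five futures of one SSP) are
plain arithmetic means and satisfy the identity
mean(all 10) = mean of the two pathway means.

## Ensemble suitability modelling

Presences are deduplicated to one *valid occurrence* per grid cell
(half-open cell membership: a point on a shared edge belongs to the
higher-index cell). The protocol is 5 pseudo-absence scenarios × 15
repetitions × the configured algorithms; each combination uses a
stratified 70/30 calibration/test split (round(0.7·n) per class in
calibration). Pseudo-absences default to max(100, 10 × presences) cells
drawn uniformly without replacement from the non-presence domain,
independently per scenario.

The native learner is a logistic regression fitted by iteratively
reweighted least squares (deviance tolerance 1e-8, ≤ 100 iterations).
Perfect separation — common with a dozen presences on a clean niche — is
detected by a diverging linear predictor, flagged, and predictions are
clipped to [1e-6, 1 − 1e-6]; the member is kept. Random-forest and other
learners attach through the `fit(X, y)` / `predict -> [0, 1]` contract
(an adapter over scikit-learn is included), so the pipeline's correctness
never depends on external fitting code; the default configuration is
logistic-only.

Each member is scored by TSS at its own best threshold on its own test
split, the threshold scanned over midpoints of the unique test scores
(ties resolve to the lowest candidate; a single unique score is its own
candidate, giving TSS 0). Members with TSS > 0.8 (strict) enter the
ensemble with weights proportional to TSS. The ensemble's own
minimum-suitable-habitat threshold is the best-TSS threshold of the
ensemble's predictions pooled over the included members' test splits,
rescaled to 0–1000; its pooled-test TSS is reported alongside. How the
original modelling framework pooled member thresholds into its final
binarization value is not documented, so this package's threshold is an
ensemble-level quantity by construction, and the published threshold value
is not a reproduction target.

## Predictor selection

Two-stage filter on the layer stack: while any pair has |Pearson r| above
0.7, drop — from the highest-|r| pair — the member with the larger mean
|r| to all remaining layers (tie: the layer later in input order); then
drop the largest-VIF layer until all VIF < 10. VIF_j = 1/(1 − R²_j) from
the OLS regression of layer j on the others plus intercept; exact
collinearity yields an `inf` sentinel. Correlations use pairwise-complete
cells, VIF listwise-complete. Both constraints are asserted on the kept
set after every run, and selection is idempotent. The original filter
delegates removal order to an external routine without documenting it, so
equivalence is asserted on the constraint set, not on the exact kept
subset.

## Demography

Young/adult classification at stem length ≤ 30 cm; ages from
length × 0.6 leaves cm⁻¹ / 3 leaves yr⁻¹. Skewness defaults to the
moment-form g1 = m₃/m₂^{3/2} with the adjusted b1 estimator selectable —
the published table's estimator is unverifiable without the raw data.
Occupied area is the convex hull (shoelace area via Qhull) or, given an
alpha radius, the alpha-shape (union of Delaunay triangles with
circumradius ≤ alpha); `alpha="auto"` uses 2× the mean nearest-neighbour
distance, since no alpha is documented for the original polygons. "Mean
distance between plants" is read as the mean over all n(n−1)/2 pairs
(nearest-neighbour mode selectable; the source is ambiguous). Degenerate
inputs are sentinels, not exceptions: < 3 or collinear points give area 0
with a flag, densities over zero area are NaN, the sd of one pairwise
distance is NaN. Size-structure curves are Gaussian KDEs rescaled to
peak 1 (Scott bandwidth by default).

## Association models

* **Linear** (population level): OLS with the overall F on (1, n−2) df,
  R², 95% slope CI, and a Shapiro–Wilk residual check.
* **Binomial** (young proportion): logit-link GLM on aggregated
  (young, adult) counts — equivalent to weighting each population's
  proportion by its census size. The unweighted-proportion variant is
  offered but non-default: proportions from censuses of 4 and 298 plants
  are not equally precise, and only count weighting yields Wald statistics
  of the magnitude the population data produce. The reported pseudo-R² is
  McFadden's ratio computed from deviances, 1 − D_model/D_null, i.e. both
  log-likelihoods referenced to the saturated model — the natural form for
  grouped binomial data and the convention that matches the published
  values; the raw-likelihood ratio 1 − ℓ_model/ℓ_null differs markedly on
  grouped counts and does not.
* **Robust linear** (plant level): MM-type estimator — S-estimate by
  elemental-pair resampling scored by the 50%-breakdown bisquare M-scale
  (c ≈ 1.548), then IRLS refinement with the 95%-Gaussian-efficiency
  bisquare (c = 4.685) at fixed scale. The slope test is a robust Wald
  statistic reported as F on (1, n−2) df using the standard M-estimator
  asymptotic covariance; the fit measure is a bisquare-weighted R². How
  the original analysis derived its robust "F" is undocumented, so its
  printed values are not reproduction targets; the estimator is instead
  validated by its efficiency (clean-data slope within 1% of OLS) and
  breakdown behaviour (slope shift < 5% under 10% gross high-leverage
  contamination, where OLS shifts > 20%).

All p-values are two-sided and uncorrected, matching the source analysis.
Slope comparisons between scenarios use 95% CI overlap with closed
intervals (touching endpoints overlap).

## Synthetic study system

The real coordinates are withheld, so the generator builds a system with
the same structure at the same sizes: 13 populations with the published
plants-per-population vector (total 1615), four standardized predictor
layers on a 32 × 32 grid of 1 km cells, and 10 futures (5 GCM analogues ×
2 pathways).

* **Landscape.** Each layer is white noise convolved with an isotropic
  Gaussian kernel (range 4 cells) and standardized; the niche axis
  (`bio03`) additionally carries a south-to-north linear gradient
  (amplitude 2.0 sd) — a landscape whose dominant climate axis is
  latitudinal. Spectral or other field generators would be equally valid;
  convolution was chosen for simplicity and per-seed determinism.
* **Niche.** Suitability is a product of per-layer Gaussian kernels. The
  niche is an *edge* niche: center at the 97th percentile of the gradient
  layer, width 0.5 sd — the regime of a trailing-edge endemic holding the
  favourable margin of the landscape, and a response a monotone learner
  can represent. The other layers get wide (2.5 sd) kernels: mild
  structure, not strong constraints.
* **Futures.** Warming/drying is a negative shift of the gradient layer:
  −0.35 sd (SSP1-RCP2.6) and −0.6 sd (SSP5-RCP8.5), each GCM analogue
  adding a deterministic jitter (sd 0.08) plus cell-level noise
  (sd 0.05). These magnitudes put the computed CCVI near +1 over the
  occupied cells — populations just past their survival minimum, the
  regime the published per-population means (≈ 0.95–1.09) describe —
  rather than deep in saturation where all gradation is lost.
* **Planted vulnerability.** Population centers are drawn from the top
  suitability decile, spread along the gradient. Each center cell's
  *true* future suitability under the expected shift is computed from the
  niche kernels; v_k maps the negated values linearly into [0.5, 1].
  Coupling is therefore through geography — recovering it requires the
  fitted ensemble and the index, not a label lookup — and the planted
  signal is linear in the quantity the pipeline estimates.
* **Censuses.** Stem lengths are gamma (positivity and the right skew the
  real censuses show), with shape/scale solved per population so the mean
  is 130 − 100·v_k cm and P(length ≤ 30) equals the planted young
  fraction logit⁻¹(−3.0 + 2.8·v_k). Those intercepts put the young
  fractions in 0.17–0.45, the span of the published censuses, and imply
  gamma shapes whose sd/mean ratios match the published stem summaries.
  Adults fruit with probability 0.37 (the published fruiting/adult ratio)
  or flower with 0.2; plants ≤ 30 cm flower with probability 0.03,
  below the < 5% flowering rate reported for that size class. Plants
  scatter around their center with sd 30 m, giving hull areas and
  inter-plant distances of the published order while the 13 populations
  occupy ~13 one-km cells (the study's 13 populations gave 14 valid
  cells).

**What the validation shows.** With these defaults the full chain
(simulate → select → fit ensemble → project → CCVI → demography →
associate) recovers the planted negative stem slope and positive
young-fraction slope, both at p < 0.05, in ≥ 80% of 50 seeded replicates
(≈ 65 s total; each replicate ≈ 1.3 s at the default problem size).
The binomial channel recovers almost always; the linear channel is the
marginal one — unsurprisingly, since a 13-point regression against an
estimated index is exactly as under-powered here as the published
analysis's own p = 0.040 suggests. What it does *not* show: robustness to
niche shapes a monotone learner cannot fit (interior optima on the
sampled range), to spatially biased sampling, to observation error in
stem lengths, or to real bioclim covariance structure — the layers are
abstract standardized predictors, not emulations of specific bioclim
semantics.

## Numerical conventions

Coordinates are planar meters, 0-based cell indices, cell-center
registration, half-open cell membership (boundary points belong to the
higher cell), row 0 at the southern edge in memory, northern-row-first in
ESRI ASCII files (missing data −9999, NaN in memory). Suitability is
integer 0–1000 at output, float [0, 1] internally. IRLS tolerances:
1e-8 on deviance (logistic), 1e-10 on coefficients (robust M-step),
100 iterations each; the S-stage uses 500 elemental pairs from a seeded
generator. Gamma shape solving brackets [0.05, 200] and clamps
unattainable young-fraction targets to the nearest attainable value.
All generators and the pipeline derive their streams from a single seed
via `numpy.random.SeedSequence` spawning, so every product is
reproducible bit-for-bit from one integer.

## Known limitations

The alpha-shape area sums triangle areas, which for very sparse alpha can
undercount hole boundaries relative to polygon-set implementations. The
ensemble threshold is defined on pooled test predictions, which is one of
several defensible conventions. The robust F and robust R² follow this
package's documented definitions and are not interchangeable with other
software's outputs. Synthetic within-population spatial spread is a
single isotropic scatter; real populations are patchy and elongated.
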