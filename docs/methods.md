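# Methods

This note documents the models and procedures implemented in `scalescape`,
the assumptions they make, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## Rasters, buffers, patches

Landscapes are categorical grids with square cells (default 5 m grain, the
resolution at which forest-inventory polygons are typically rasterized:
coarse enough to drop streams and narrow seismic lines, fine enough to
resolve retention patches and wide linear features). Conventions, all
configurable:

- **Cell-in-buffer rule.** A cell belongs to a circular buffer iff its
  centre lies strictly within the radius — the dominant raster-GIS
  convention; it makes retained-cell counts reproducible across
  implementations. A 100 m buffer on 5 m cells covers the true disc area to
  well under 3%.
- **Connectivity.** Patches are maximal same-class components under
  8-connectivity (the FRAGSTATS default); 4-connectivity is available.
- **Perimeter vs edge.** A patch's perimeter counts all faces adjoining a
  different class, nodata, or the clipped boundary, keeping PAFRAC
  well-defined on clipped discs. Edge *density*, by contrast, counts only
  internal faces between data cells of different classes, so the artificial
  circle outline never contributes edge.
- **Core area.** Morphological erosion by an edge depth of one cell (5 m) by
  default; the depth must be a multiple of the cell size. Grid and nodata
  boundaries are edge, never core.
- **Nodata.** Permanent disturbances (roads, gravel pits) are nodata and
  excluded from every denominator.

## Configuration metrics

Edge density (m/ha), SHDI, CONTAG (%), PAFRAC and CAI CV (%) follow the
FRAGSTATS landscape-level definitions. Adjacency tallies use the
double-count convention (each internal face tallied from both sides);
boundary and nodata faces are excluded. CV uses the population (N-)
standard deviation, matching the FRAGSTATS CV definition.

Undefined values are data, not exceptions: CONTAG needs ≥ 2 classes, PAFRAC
needs ≥ 10 patches and non-degenerate perimeter variance, CAI CV needs a
non-zero mean core index. Each undefined `MetricValue` carries its reason so
model scans can skip and report them. This mirrors how sparse fine-scale
buffers behave in real mosaics, where PAFRAC is typically incomputable at a
50 m radius but computable at broad extents.

A counterintuitive property of CONTAG worth knowing: with two classes at
equal cover, both a perfectly aggregated split and a perfect checkerboard
converge to 50% (their adjacency distributions are equally concentrated);
CONTAG approaches 0 only for *mixtures* of like and unlike adjacencies
(random speckle) and 100 only as one class dominates a single blob. Tests
assert the orderings that actually follow from the formula.

## Nested richness

Richness at response radius r counts distinct species with at least one
detection at distance ≤ r (ties at exactly r included). The default schedule
is 50–350 m every 25 m (13 extents, 0.79–38 ha); 350 m is around the maximum
detection distance of many songbirds on modern recording units. Counts are
naive — no detection-probability correction — and monotone non-decreasing in
radius by construction. Species filtering (e.g. to passerines) is the
caller's responsibility.

## The global model and the scale-of-effect scan

For response extent *i* and landscape extent *j ≥ i*:

    log E[richness_i] = β₀ + β_m·metric_j + β_u·uplands_j + β_g·GDD
                        + β_a·autocov + α_year,   α_year ~ N(0, σ²_α)

- Predictors are z-scored per fitted dataset, so coefficients are
  comparable across metrics and extents. Zero-variance nuisance covariates
  (uplands is often exactly 1 inside harvest blocks at fine extents) are
  dropped; a zero-variance metric invalidates the extent.
- **Family** is chosen per fit from the Pearson dispersion of a Poisson fit
  (negative binomial above 1.5, configurable). NB fits estimate the size θ
  by maximum likelihood (NB2); θ can be held fixed, in which case the NB
  likelihood degenerates to Poisson as θ → ∞.
- **Random intercept.** The survey-year intercept is integrated by Laplace
  approximation: per-group conditional modes by damped Newton (the inner
  problem separates by group), outer L-BFGS-B over (β, log σ_α[, log θ]),
  SEs from the numerical Hessian. Agreement with `lme4::glmer`'s Laplace fit
  is verified in the test suite (coefficients to ~1e-3, log-likelihood to
  0.5). Whether the intercept stays in the model is decided once per
  response extent by simulation-based residual diagnostics (below).
- **Spatial autocovariate.** Fitted values of a low-rank thin-plate-type
  penalized smooth (radial basis r² log r at 30 deterministic knots,
  unpenalized affine null space, ridge penalty by GCV with the usual γ = 1.4
  inflation) of the deviance residuals of the non-spatial model. Two guards
  address the circularity inherent in regressing a model on a smooth of its
  own residuals, which otherwise yields ~35–45% spurious significance under
  spatially white residuals: the covariate is the smooth's *leave-one-out*
  predictions, and it enters only when those predictions beat the
  intercept-only leave-one-out predictor of the residuals (otherwise it is
  identically zero and drops from the design). Measured on white noise the
  downstream autocovariate CI covers zero in ~96% of replicates, while an
  implanted smooth trend is recovered with correlation > 0.7 in 20/20.
- **Marginal R².** Nakagawa–Schielzeth: σ²_f/(σ²_f + σ²_α + σ²_dist), with
  σ²_f the variance of the fixed linear predictor (intercept excluded) and
  σ²_dist by the lognormal approximation ln(1 + 1/λ [+ 1/θ]) by default
  (delta and trigamma variants available); λ is estimated by the mean
  response.
- **Tiered selection.** Among extents with p ≤ 0.05 for β_m, take the
  highest marginal R²; failing that, 0.05 < p ≤ 0.1; failing that, all
  remaining extents. R² ties break toward the smaller extent (conservative
  locality).
- **Structures.** Additive, metric × uplands interaction, and
  metric + metric² are compared by pairwise likelihood-ratio tests against
  the additive model (each adds one term, so χ²₁); no significant
  improvement keeps the additive model, and if both alternatives improve,
  the higher log-likelihood wins (they have equal complexity and are not
  nested in each other).

### Residual diagnostics and the random-effect decision

Randomized-quantile (PIT) residuals against 250 simulations from the fitted
model (random effects re-drawn per simulation), then three α = 0.05 tests:
dispersion (observed Pearson statistic against its simulated distribution,
two-sided), residual spatial autocorrelation (Moran's I with
inverse-distance weights, normal approximation), and uniformity
(Kolmogorov–Smirnov). The year intercept is retained iff it resolves a
violation detected without it, or its estimated variance exceeds a floor
(default σ²_α > 0.05). All statistics are reported either way.

## Domains of scale

Per metric, selected landscape extent is smoothed on response extent with an
independent penalized cubic B-spline (no shared global smooth):

- **Basis.** 30 B-splines over the data range — deliberately more than 13
  points could support unpenalized. A coarse basis (say 6 splines) has ~12 ha
  knot spacing, smears any regime change over that scale, and dislocates the
  derivative transition by several hectares; the rich basis resolves a kink
  to roughly the data spacing while the penalty controls wiggliness.
- **Penalty.** Second-order *divided* differences at the Greville abscissae,
  so linear functions are exactly in the nullspace despite the clamped-knot
  boundary (index-wise differences are not nullspace-correct there).
- **Smoothing parameter.** Restricted maximum likelihood over a log grid;
  REML is far more stable than GCV at n ≈ 13. The posterior covariance is
  σ²_REML (B'B + λP)⁻¹ with σ²_REML = (RSS + λβ'Pβ)/(n − 2), floored
  relative to the data variance so exactly-interpolable (noise-free) inputs
  stay well-posed.
- **Derivative.** Central finite differences with a 1 ha step on a 1 ha
  grid, with pointwise 95% CIs from 1000 draws of the coefficient posterior.
  The grid is trimmed by half the median data spacing at each end: CI
  widening at the extreme ends flips significance for want of data, and
  those flips are edge artifacts, not domain transitions.
- **Boundaries.** A boundary is called at every adjacent change of the
  derivative's significance state (positive / non-significant / negative by
  CI versus zero), located at the midpoint of the transition interval, with
  both flanking CIs recorded. Every such transition has a significant flank
  whose CI excludes zero — exactly the filter for a domain change.
- **Persistence rule.** The first boundary is always kept; later boundaries
  are kept only when the significant flank's CI bound nearest zero exceeds a
  margin (default 0.1 ha/ha). Oscillations whose CIs merely graze zero are
  grouped into the surrounding domain — making explicit and configurable a
  grouping step that is otherwise applied by judgment.

Measured operating characteristics (three independent seed streams): on 1:1
null scans with noise SD 2 ha, no boundary is selected in 24–25 of 25
replicates; with an implanted two-regime truth (slope 3 below 12 ha, flat
above, noise SD 2 ha) the selected boundary lands within ±3 ha of the
threshold in 16–19 of 20 replicates.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure of a managed boreal mosaic at 5 m
grain: a Voronoi-tessellated matrix of mature stands (conifer / deciduous /
mixedwood), smoothed-noise lowland pockets, harvest blocks with lognormal
sizes (mean 11 ha, minimum 7 ha — the shape of real cutblock registries),
block outlines perturbed by smoothed noise under a single shape-complexity
knob, retention islands inside blocks, wide vegetated linear features, and
10-year regeneration age classes. Sites are placed inside harvest blocks
with ≥ 300 m pairwise spacing and ≥ 150 m clearance to the (morphologically
closed) harvest edge, mirroring field protocols; clearance treats retention
islands and linear slivers as interior to the harvest area, since a 150 m
clearance to *every* non-harvest cell is geometrically unsatisfiable in
blocks near the 11 ha mean (a circular 11 ha block has a 187 m radius).

Communities are induced mechanistically rather than drawn from the
regression: each of 30 species holds territory centres from an inhomogeneous
Poisson process whose log intensity includes a baseline density (lognormal
across species around 0.016 territories/ha, giving mean detected richness
around 8–12 at the full 350 m radius), an effect of a configuration metric
at the implanted extent E* (default: edge density, +0.3 per SD at 15 ha), a
GDD gradient (north–south plus noise), survey-year effects (SD 0.2 over five
years), a Gaussian random field (exponential covariance, 1500 m range,
SD 0.15) and a unit-mean gamma site frailty (variance 0.1) that produces
overdispersion. Detection is the nearest territory centre within 350 m, so
distance-truncated richness is monotone by construction. Because the
downstream count regression is then only an approximation of the generative
process — as in real studies — a separate *direct-GLM* generator draws
counts straight from the regression for exact coefficient-recovery and CI
coverage tests.

Not emulated: distance-estimation error (synthetic detections carry true
distances), detection probability declining with distance (so synthetic
accumulation curves keep rising where real ones flatten beyond ~20 ha),
species identity and trait structure, temporal within-season dynamics, and
vector-data artifacts of rasterization. Passing tests therefore demonstrate
that the *statistical machinery* recovers implanted structure under
realistic spatial confounding — not that any particular ecological effect
size is realistic.

## Numerical choices and degenerate inputs

- Determinism throughout: every stochastic routine takes a seed; master
  seeds spawn per-stage seeds via `SeedSequence`, and persisted CSVs use
  round-trip float formatting so re-running any pipeline stage from files
  reproduces in-memory results bit for bit.
- GLM fits delegate to statsmodels; the mixed model caps Newton steps at ±5
  for stability and bounds log σ_α ∈ [ln 1e-4, ln 10], log θ ∈ [ln 1e-3,
  ln 1e6].
- Rank-deficient designs raise an error naming the collinear terms;
  non-convergence is flagged on the fit, never raised.
- Coincident site coordinates collapse the spatial smooth basis and raise
  with guidance to jitter.
- Problem sizes in tests and the acceptance script (raster 1500²–2300²
  cells, 30–100 sites, 20–50 replicates, coarse 25–50 m radius schedules)
  are chosen so full recovery experiments run in minutes while leaving the
  estimators in the regime the reference design uses; the radius schedules
  are always inputs, and all row counts derive from them.

## Known limitations

- The scale-of-effect grid is only as fine as the radius schedule; selection
  error is bounded below by half the local extent spacing.
- The tiered rule inherits the multiple-comparison character of scanning
  many extents; as in the framework it implements, inference should rest on
  consistency across response extents, not on any single selected model.
- The Laplace approximation is adequate for one random intercept with
  several groups; it is not a general GLMM engine.
- CONTAG's two-class degeneracy (above) limits its contrast in landscapes
  dominated by two cover classes.
- The autocovariate absorbs broad residual trends; it is not a substitute
  for an explicit spatial covariance model when fine-scale dependence
  matters.
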