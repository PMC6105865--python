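# Methods

`geodens` implements, end to end, a virtual sampling and ecological
regression design for estimating the spatial density of geosocial-app users
over a metropolitan region, together with a synthetic-geography generator
that makes every stage testable without any external data.

## The estimand and the sampling protocol

The quantity of interest is **app-user density**: the number of app users
visible within a 1-mile radius of a location, divided by the land area
within that radius, rounded to the nearest integer (users per square mile).
Densities are observed at the nodes of a systematic 2-mile lattice laid over
the study region, so the 1-mile discs are pairwise tangent and no user can
fall in two buffers. Sampling order is randomized, and each location is
assigned to one of six evening slots (Monday–Wednesday, before/after 8 pm);
slot indicators are forced into every regression to absorb time-of-day and
day-of-week variation in app activity.

A location's observation comes from the app's screen: a list of nearby
profiles ordered by increasing Euclidean distance, in which roughly a
quarter of users withhold their displayed distance. The counting rule
handles these hidden profiles by position:

* a hidden profile listed **before** the farthest displayed profile within
  the radius must itself be within the radius → counted;
* a hidden profile listed **after** the nearest displayed profile beyond
  the radius must be outside → not counted;
* a hidden profile between those two anchors (or with no anchor at all) is
  **ambiguous** and is never counted.

This rule is exactly the constraint-satisfaction answer to "is every
distance assignment consistent with the displayed ordering on one side of
the radius?", and the test suite verifies that equivalence by brute force.
Users are de-duplicated across the campaign by id, first-seen (lowest
sampling order) wins. Buffers whose disc contains no land are dropped with
a warning.

## Areal covariates

Explanatory variables live on irregular census-style **dissemination areas
(DAs)** — population, population density, and male-population age, income,
marital, education, employment, low-income (LICO), immigration, visible
minority and household-size measures. Because the outcome lives on buffers,
each buffer covariate is the combined area- and population-weighted average

    x̄_i = Σ_j w_ij x_j / Σ_j w_ij,   w_ij = P_j · a_ij / A_j,

where `a_ij` is the area of DA `j` inside buffer `i`, `A_j` the DA's area
and `P_j` its population. No closed form for "combined area and population
weighting" is universal, so this defining formula is fixed here and stated
prominently in `geodens.areal`. Covariates enter models on conventional
scales: population density per 100 persons/km², income per Can $1000,
percentages as 0–100, age in years, household size in persons. Weighting
uses total (not male) population. Quantile summaries use the
linear-interpolation rule.

## Regression machinery

Counts are modelled with a Poisson GLM (log link), fitted by iteratively
reweighted least squares (deviance-change tolerance 1e-8, 100-iteration
cap) with the covariance taken as the inverse Fisher information at the
optimum. The default outcome is the rounded density; a count outcome with a
log land-area offset is available (`--offset-mode`) and is the
correctly-specified variant for the generator's point process (see
*Calibration* below). On top of the fit:

* **Backward AIC elimination** — from the full model, repeatedly remove the
  candidate whose deletion most lowers AIC, while it lowers AIC; the
  six-level sampling-time block and intercept are never removable, and the
  block would drop as one unit. Exact AIC ties (1e-10) resolve to the
  earlier candidate.
* **Likelihood-ratio tests** between nested fits, `2Δℓ ~ χ²_Δk`
  (identical fits return p = 1 by convention).
* **McFadden pseudo r²**, `1 − ℓ/ℓ₀`, against the intercept-only model
  (the null does *not* include the forced time term; both conventions are
  defensible, this one is fixed and documented).
* **Bonferroni outlier screen** — studentized deviance residuals
  `r_i/√(1−h_i)` with GLM hat values, two-sided standard-normal p-values
  multiplied by n, flagged below α = 0.05. A buffer flagged under the
  density-only model but not under the selected model is a "geographic area
  of interest" explained by neighbourhood composition.
* **IRR reporting** — `exp(β)` with Wald 95% intervals `exp(β ± 1.96·SE)`
  and percent change `100(IRR − 1)` rounded to the nearest integer percent.

No overdispersion adjustment is applied (plain Poisson by design); the
quasi-Poisson scale (Pearson χ²/df) is logged as a diagnostic only.
Profile-likelihood intervals were rejected in favour of Wald intervals for
fidelity to the symmetric-on-log-scale intervals such analyses report.

## The synthetic world

The generator emulates the statistical structure the analysis assumes, not
any real geography:

* **Tessellation** — Voronoi cells of uniform seed points clipped to the
  rectangular region: irregular, space-filling, cheap. Cells partition the
  region exactly (area conservation is asserted at 1e-6 relative).
* **Covariate fields** — independent Gaussian white noise at DA centroids,
  smoothed with a Gaussian kernel (default bandwidth 4 miles, giving
  neighbourhood-scale autocorrelation), then affinely mapped so the
  empirical median and IQR match census-plausible anchors for a mixed
  rural/urban metropolitan region (e.g. household size 2.8 (2.6–3.0),
  population density 331.6 (59.2–1807.0) persons/km², mapped on the log
  scale for skew and capped at 20,000 persons/km², a dense-tower extreme).
  Percentages are clipped to [0, 100]. In the infinite-bandwidth limit all
  DAs receive identical values. Population is density × area by
  construction, so the two can never contradict each other.
* **Users** — an inhomogeneous Poisson process, constant within DA:
  `count_j ~ Poisson(λ_j · area_j)` with
  `log λ_j = β₀ + Σ_k β_k x_jk` on the model scale, points uniform in the
  cell. Default coefficients are effect sizes typical of this literature
  (e.g. IRR 0.26 per household-size unit, 1.08 per % not married, 1.03 per
  100 persons/km²), with β₀ = 0.1 calibrated so the *median* campaign
  counts on the order of two thousand profiles — the yield scale of a
  real metropolitan evening campaign. Because the density field is
  lognormal, total yield varies widely between worlds; that spread is a
  feature, not noise to be suppressed.
* **Privacy** — `shows_location ~ Bernoulli(1 − p_hidden)` independently,
  default `p_hidden = 0.254`; a spatially varying hook
  (`p_hidden_field(x, y)`) exists but defaults off.
* **Time slots** — slot effects are log relative activity levels (defaults
  follow the fitted sampling-time IRRs: 1, 2.16, 2.00, 2.28, 1.15, 1.13).
  They act by *thinning*: a user is visible during slot `s` with
  probability `exp(e_s − max e)`. Fitted slot coefficients therefore
  estimate `e_s − e_ref`, and the model intercept absorbs `−max e`.
* **The app screen** — `build_listing` sorts users by true distance (ties
  by id), hides distances of privacy-flagged users, and optionally
  truncates to a screen length. The default is *no* truncation: the
  protocol counts every profile within the radius, and at realistic
  densities any plausible screen cap would bind inside the radius and
  silently censor dense buffers. The campaign's hot path cuts each listing
  just after the first displayed distance beyond the radius, which provably
  cannot change any label.

What the generator does **not** emulate: real street geography or
coastline (land is simply the tessellated rectangle), spatially correlated
privacy behaviour, user movement between sampling slots, multi-app overlap,
census suppression of small areas, or any real census values beyond the
anchor quantiles. Passing tests therefore demonstrate that the *pipeline*
is correct and calibrated under its assumed model, not that the
substantive field findings generalize.

## Calibration, and what honest recovery looks like

Two statistical facts about this design are worth recording because they
are properties of the *design*, not bugs:

1. **The rounded-density outcome is underdispersed.** A density is a count
   scaled by ~π square miles of land, so its variance is roughly mean/π —
   a plain-Poisson model overstates its variance and Wald intervals become
   conservative (measured quasi-Poisson scale ≈ 0.3–0.5). Estimates are
   unaffected; intervals are wide.
2. **The areal-weighted covariate is an aggregated proxy.** The buffer
   covariate `x̄_i` is not the value that generated the intensity inside
   the disc; the aggregation residual behaves like extra-Poisson variation
   between worlds (quasi-Poisson scale ≈ 2 for the offset-count model
   across fresh worlds). End-to-end coefficient estimates are nearly
   unbiased and recover every substantive effect's sign, but their
   between-world spread exceeds the Fisher promise — the ecological-
   inference caveat in numbers.

Consequently, the formal calibration checks (95% Wald coverage across 200
replicates; null LRT p-value uniformity across 500 replicates, KS at the 1%
level) are run where a Poisson likelihood is correctly specified: outcomes
simulated from the model at the default campaign's design matrix with the
generator's true coefficients. End-to-end point-process recovery is tested
separately as near-unbiasedness plus sign recovery over fresh worlds.

## Problem sizes used by the validation suite

Default campaign: 32 × 32 miles, 1,200 DAs, 256 sampling locations.
Coverage uses 200 model-based replicates at that design; LRT uniformity
500; end-to-end recovery 20 fresh worlds; elimination behaviour 40–100
design-level replicates; geometric oracles use 10⁵-point Monte-Carlo
integration. Smaller 12–16-mile worlds (36–64 buffers, baseline intensity
raised so counts stay informative) exercise the pipeline plumbing.

## Known limitations

* Plain Poisson + Wald inference inherits both dispersion mismatches above;
  a quasi-likelihood or bootstrap interval would be the natural extension.
* The hidden-profile rule treats privacy flags as independent of location;
  spatially clustered privacy would bias counts downward where it clusters.
* Ambiguous profiles (≈3–5% of hidden ones in synthetic campaigns) are
  dropped, a small conservative undercount concentrated near each buffer's
  rim.
* Greedy backward AIC does not search all subsets and can keep
  noise terms at the usual `P(χ²₁ > 2) ≈ 0.157` per-term rate.
* All geometry is planar; no projection handling is attempted.
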