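# Methods

## Fire frequency from a gridded burn history

The fire record is a regular grid (default cell size emulates a 500-m
burnt-area product) observed over a window of *T* years (default
*T* = 22.0, representing a November-to-October satellite record). Two
events in one cell on the same date collapse to one, since a monthly
burn-scar product cannot resolve them.

**Mean event rate (primary estimator).** Occurrence records are mapped to
cells with half-open `[edge, edge + size)` membership on both axes, so a
point exactly on a shared edge belongs to the cell whose low edge it
equals; duplicate records in a cell count once. For a species occupying
*n* cells with *N* total recorded fires,

    F = (N / n) / T × 100   (fires per century).

This assumes a constant (homogeneous-Poisson) event rate through time —
fuel feedbacks that accelerate or suppress fire would change the absolute
values but not the ranking of species. Species with fewer than
`min_cells` cells (default 10) are excluded with reason `too_few_cells`,
checked first; species whose occupied cells are all unburnt are excluded
with reason `all_unburnt`. The two counters are logged separately because
they answer different bookkeeping questions.

**Censored Weibull median FRI (comparison estimator).** Per cell with
events t₁ < … < tₙ in window [a, b], the intervals are: the opening
interval (t₁ − a), closed intervals (tᵢ₊₁ − tᵢ), and the right-censored
trailing interval (b − tₙ); an unburnt cell contributes one censored
interval of length *T*. Intervals are pooled across a species' cells and
a Weibull(k, λ) is fitted by maximum likelihood — closed intervals
contribute the log density, censored ones the log survival −(t/λ)ᵏ — over
(log k, log λ) by Nelder-Mead with multi-starts from the exponential
solution (k = 1, λ = total exposure / closed count, the closed-form MLE
under right censoring). The median fire-return interval is λ(ln 2)^(1/k)
and converts to 100/median fires per century.

*Censoring the opening interval is a modelling choice the window-truncated
record does not settle.* The default (`first_interval="censored"`) is the
conservative survival-analysis convention; under a constant-rate truth it
lengthens fitted intervals, so the survival-method frequency sits
systematically below the mean-event-rate estimate — the direction of skew
reported for this estimator pair on real data. The alternative
(`first_interval="closed"`) treats the opening interval as a complete
draw, which is exact for a memoryless process and makes the two
estimators agree (a property the test suite checks at 3 SE under Poisson
simulation). Fits with fewer than two closed intervals are refused unless
the shape is fixed.

## Occurrence cleaning

Records pass a fixed battery in a documented order — georeferencing,
basis of record, collection year, zero coordinates, coordinate bounds,
decimal precision, coordinate uncertainty, pre-existing issue flags,
sea/centroid/capital/institution proximity (great-circle, supplied point
sets), duplicates — and each removed record is charged to the *first*
filter it fails, so `kept + Σ removed = input` exactly and cleaning is
idempotent. Decisions that the rule set leaves open:

* "post-1900" is read strictly: records with year ≥ 1901 are kept.
* Uncertainty uses strict `>` 10 000 m, so exactly 10 000 m survives.
* Decimal precision is judged on verbatim coordinate text when available;
  from floats alone, a coordinate equal to its 1-decimal rounding within
  1e-9 is deemed low-precision (trailing zeros are unrecoverable).
* The duplicate key defaults to (species, longitude, latitude, year);
  the first occurrence is kept.
* Issue flags (`COUNTRY_COORDINATE_MISMATCH`, `RECORDED_DATE_UNLIKELY`)
  are consumed as upstream annotations, not recomputed.
* Reference point sets (country/capital centroids, institutions) are
  user-supplied, not bundled.

## Trait classification

A species is a **resprouter** when ≥ 30 % of its resprouting observations
record full or partial resprouting, and a **seeder** when ≥ 30 % record
postfire recruitment; ties at exactly 30 % classify positive, and a
species with no observations of a trait is *missing*, never negative —
denominators everywhere are species-with-data. Duplicate
(taxon, trait, value, source) rows collapse before classification;
distinct sources count as independent observations. Growth form maps
woodiness vocabulary values through an editable table with token
fallback; conflicting pure values (woody and herbaceous both observed)
are ambiguous, and semi-woody/ambiguous species are flagged for
exclusion. The shipped combined-value mapping (e.g. "herbaceous
semi_woody" → semi-woody) is a declared default, not an authoritative
vocabulary, and is overridable. Life history resolves to perennial when
any observation says perennial. Species means of LMA (g m⁻²) and leaf N
(mg g⁻¹) divide by the number of observation rows, ignoring replicate
counts, because most rows are raw single measurements.

## Regression

The fire-response model is a binomial GLM (logit link) on a raw —
not orthogonal — quadratic in x = log₁₀(F), fitted by IRLS (relative
deviance tolerance 1e-10, 100 iterations); raw polynomials keep the
intercept interpretable at F = 1 fire per century and make the printed
odds-ratio column exactly e^coefficient. Growth form enters with
treatment coding, herbaceous as reference. Confidence intervals are Wald;
odds-ratio CIs exponentiate the Wald bounds. Quasi-complete separation is
detected (IRLS warning or runaway coefficients) and flagged, never
silently returned. Tjur's R² is |mean p̂ among TRUE − mean p̂ among
FALSE|. Curve CIs are computed on the logit scale and transformed, so the
band respects (0, 1) and contains the point estimate. The peak
F* = 10^(−β₁/2β₂) is reported only when the group's curvature is
negative; otherwise a monotone flag.

Leaf-trait models are OLS of log₁₀(species mean) on strategy × growth
form. Pairwise estimated-marginal-mean contrasts use the fit covariance
and residual df (no Satterthwaite); Tukey uses the studentized-range
distribution over the family of compared means, Bonferroni multiplies by
the family's contrast count. The default family is the two means within
one growth form (conditioning on group, where neither adjustment bites);
`family="all"` pools all four cell means.

## Synthetic data generator

The generator emulates the analysis inputs with known truth:

* **Fire history**: per-cell counts Poisson(r(c)·T), times uniform on the
  window. The default rate field is a log-smooth gradient along one axis
  spanning 0.002–0.5 events yr⁻¹ (F ≈ 0.2–50 fires/century), similar in
  span to an observed continental gradient but truncated below so modest
  synthetic ranges still accumulate events.
* **Species ranges**: contiguous rectangular blocks placed uniformly;
  occurrence points jittered inside occupied cells. No dispersal realism
  or spatial aggregation of records is attempted. Pipeline default is a
  16×16-cell range with 200 occurrence records, so a species' measured
  log₁₀F carries ≲0.1 dex sampling noise — the regime of real ranges
  spanning thousands of burnt cells. True F is the occupied-cell mean of
  100·r(c), recorded exactly.
* **Fire traits**: a latent label per species drawn Bernoulli(p) with
  p = logistic(β₀ + β₁x + β₂x²) at x = log₁₀(true F); the default curves
  use the published herbaceous resprouting scale (0.88, 0.70, −1.17) and
  the seeding scale (1.55, 0.66, −1.22). Each species emits 5 categorical
  observations with distinct source ids, each flipped with probability
  0.05 (symmetric; a one-sided flip emulating harder detection of absence
  is available, default off). These defaults exercise the 30 % rule —
  false-positive classification ≈ 2.3 % — while keeping species labels
  reliable enough for parameter recovery.
* **Leaf traits**: log₁₀ values Normal(group mean, sd).
* **Contaminants**: per-reason fabricated records (zero coordinates,
  pre-1900 years, low precision, high uncertainty, wrong basis, missing
  coordinates, out-of-bounds, issue flags, exact duplicates), labelled in
  the truth ledger so cleaning recall/precision is checkable exactly.

All generators are pure functions of (inputs, seed), with per-operation
streams derived from the master seed via `numpy.random.SeedSequence`.

What passing tests therefore show: the estimators and filters are correct
under the stated generative assumptions. What they do not show: behaviour
under spatially autocorrelated fire, non-constant hazard, clustered or
biased occurrence sampling, phylogenetic signal in traits, or taxonomy
mismatches — none of which the generator produces.

## Validation design and problem sizes

* **End-to-end recovery**: 3 000 species on a 200×200 grid; each fitted
  coefficient must land within 3 reported SEs of the generating values and
  the recovered peak near the analytic 10^(−0.70/(2·(−1.17))) ≈ 1.99
  fires/century. Runs in ~10 s.
* **CI calibration**: the landscape and measured fire frequencies are
  generated once (1 000 species, 120×120 grid); each of 200 replicates
  redraws noiseless trait labels from the truth curve *at the measured
  log₁₀F* and refits. Drawing at the measured predictor isolates the Wald
  machinery from predictor measurement error, which the recovery
  experiment covers separately. Expected coverage 92–98 %.
* **Oracle equivalence**: the censored-Weibull MLE is checked against a
  dense (k, λ) grid search at 0.01 resolution, and the GLM/OLS fits
  against direct likelihood maximisation / normal equations on tiny fixed
  datasets.

## Known limitations

* The constant-rate assumption is inherited, not tested; the Weibull
  comparison method shares the pooled-interval independence assumption
  across cells (no spatial autocorrelation correction).
* The per-cell strategy-proportion raster weights every species equally
  within a cell; no range-size or abundance weighting.
* Phylogenetic regression is out of scope; the species-level model table
  is exported so external tools can consume it.
* The woodiness mapping ships as a default table, not a curated standard.
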