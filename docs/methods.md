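# Methods

## Model

The package predicts a vector of k = 5 bounded prevalence outcomes per
surveyed cluster from p numeric covariates under a survey-specific
signal-plus-noise model y = f(x) + eps, eps ~ (0, Sigma), with eps i.i.d.
across clusters. f is a multivariate random forest whose node-splitting cost
is the sum of squared Mahalanobis deviations from the leaf mean,
C_L = sum (y - ybar_L)' Lambda (y - ybar_L), Lambda = Sigma^-1. Internally
the outcomes are whitened once per fit by W with W'W = Lambda (Cholesky of
Lambda, transposed), after which the cost is the plain pooled-variance (SSE)
criterion on the whitened outcomes; the two are identical by construction
and the identity is verified numerically in the tests. Leaf predictions are
componentwise means of the *original* outcome vectors (whitening affects
split choice only), forest predictions are means over trees, and the
across-tree standard deviation is reported as a per-prediction uncertainty.

With k = 1 the model reduces exactly — split for split — to a univariate
variance-criterion forest for any positive scalar Lambda; this reduction is
enforced by tests against an independently coded CART.

## Precision estimation (FGLS)

Sigma is unknown, so Lambda is estimated in a first stage analogous to
feasible generalized least squares: one univariate forest per outcome (same
T, d, dsr as the joint model), training residuals y - yhat collected, and
their sample covariance inverted. If the covariance is ill-conditioned
(condition number >= 1e8) a ridge delta * mean(diag(Sigma_hat)) is added to
the diagonal, delta starting at 1e-6 and doubling until conditioning is
acceptable; all-zero residuals (perfect in-sample fit) fall back to the
identity with a warning. In-sample residuals understate the noise scale, but
split choice is invariant to the overall scale of Lambda; only its
correlation structure matters.

## Tree growing — numerical choices

* Candidate thresholds are midpoints between consecutive distinct sorted
  values of a feature; children smaller than `min_samples_leaf` (default 2)
  are forbidden; a node does not split unless some candidate strictly
  reduces the cost.
* Per-node costs are computed with prefix sums over each candidate
  feature's sort order (O(n log n) per node). Split ties break to the
  lowest feature index, then the lowest threshold; costs within a 1e-10
  relative tolerance of the minimum count as tied so that floating-point
  noise in the prefix-sum formula cannot flip an exact tie. This makes the
  search bit-reproducible against an exhaustive oracle.
* Bootstrap resampling is on by default and feature subsampling at rate dsr
  (`max_features`) is applied per node, at least one feature per draw —
  standard random-forest practice; both are exposed as toggles.
* Degenerate inputs: a single training row yields stump trees predicting
  that row's outcomes; depth 0 yields the (bootstrap-averaged) training
  mean.
* MDI importance of a feature sums, over the splits using it,
  (n_node / n_tree) * (cost_parent - cost_left - cost_right) / n_node,
  then averages over trees; never-used features score exactly 0. Grouped
  importance sums member features per data-type group.

Defaults T = 2000, d = 4, dsr = 1/3 are the selected operating point for
the survey application; tests and the acceptance script run T = 30–200 with
the same d and dsr, sizes chosen so the full suite runs on one CPU in
minutes. Accuracy of forest means is insensitive to T well below 2000; only
the across-tree uncertainty smooths further with more trees.

## Feature engineering

* **Nearest-in-space assignment** of static covariates uses haversine
  distance on a sphere of radius 6371 km (the metric is not otherwise
  pinned down by the data sources); distance ties break to the lowest
  candidate index.
* **Seasonal z-score anomalies**: the 12 months before the survey start are
  split into four consecutive 3-month seasons counted backwards from the
  survey date (survey-anchored; a calendar-fixed toggle exists because
  either anchoring is defensible). For each season,
  z = (seasonal value at the nearest sensed cell - mu) / sd, where mu and
  sd (sample, n-1) pool all raw values observed within 100 km during that
  season; by default the pool spans the full record of the season across
  years (a window-only toggle exists). sd = 0 maps to z = 0. The feature is
  the mean of the four z-scores, invariant to shifting and positive scaling
  of the series.
* **Food prices**: per (market, commodity), mean and sample variance of the
  monthly price over the 12 months strictly before the survey start;
  commodity series missing any window month are excluded rather than
  imputed. Features are emitted per market in order of haversine distance
  from the cluster, so "market 1" always means the nearest market. Prices
  are used as reported (unit tags carried, no conversion).
* **Conflict**: events are pre-filtered to those with coordinates and
  timestamps; a survey's (event count, death count) covers events starting
  in the year before the survey start plus multi-day events ending inside
  that window, counted once, country-wide (the sparse event data do not
  support finer spatial attribution).
* **Missingness filter**, applied to each stacked train+test regime: drop
  feature columns missing in strictly more than 20% of rows, then drop rows
  with any remaining missing feature or outcome. The filter is idempotent
  and reports what it removed.

## Evaluation

* Sequential splits never use rows from the test year or later; a country
  with a single survey round produces no sequential split. Contemporaneous
  splits partition the test year into five near-equal seeded folds and add
  all earlier same-country rows to training. Both model variants see
  identical train/test rows.
* r² = 1 - SSE/SST with the baseline mean taken over the pooled observed
  test outcomes of the reporting unit (aggregate, country, or survey); a
  per-observation baseline would zero the denominator, so the scalar pooled
  mean is used. r² may be negative; constant observed outcomes make it
  undefined (reported missing with a warning).
* NRMSE = RMSE / observed outcome range of the reporting unit. By default
  the range comes from the unit's pooled test outcomes; a train-range
  alternative is exposed since either normalization is defensible.
* Country-mean summaries weight country-level metrics by pooled test-row
  counts (and the unweighted mean is reported alongside, since the two can
  differ materially). Fold-based runs additionally report across-fold mean
  and standard deviation at every level. Pooled-aggregate r² is *not* the
  weighted mean of country r² values — baselines differ — and a test pins
  this distinction.

## Synthetic worlds

The generator emulates the *structure* of a multi-country cluster-survey
study: rectangular country domains far enough apart that 100 km
neighbourhoods never cross borders; per-survey clusters drawn uniformly and
jittered uniformly in a disc (default radius 10 km, local-tangent
approximation) mimicking coordinate anonymization; smooth static covariate
fields (sums of Gaussian bumps); gridded monthly rasters with a seasonal
cycle, country-year anomalies, and cell noise; seasonal market price series
positive by construction; Poisson conflict events with >= 1 death each.
Sub-seeds per data source are fixed offsets from the master seed, so adding
or resizing one source never perturbs another's draws.

Outcomes: y = clip01(expit(alpha_j + s_j * u_j(x)) + eps). Each u_j mixes a
common standardized component shared by all outcomes (weight
`signal_share_common`, default 0.5) with an outcome-specific component; the
five prevalence indicators co-move along the same wealth/geography gradient,
and that shared structure is what joint estimation exploits. Components are
linear + one interaction in five covariates from the signal pool,
standardized so s_j is the signal standard deviation on the logit scale.
Static-geography covariates carry weight 1.0 in the pool and the seasonal
anomalies 0.4: geography dominates observed prevalence patterns and
inter-survey prevalence change is modest, so anomaly-driven year shifts are
kept secondary. Defaults alpha_j in [-1.0, 0.2] and s_j = 0.7 keep pre-noise
prevalences roughly inside (0.1, 0.8); noise is multivariate normal on the
prevalence scale (default sd 0.05 per outcome, pairwise correlation 0.5 —
the order of cluster-level sampling noise in ~25-household clusters) and the
clipped fraction is reported (< 1% at the defaults).

What the generator does **not** emulate: real spectra or spatial covariance
of the satellite products, survey sampling weights, national borders or
population distributions, spatial autocorrelation of the outcome noise, and
commodity-specific price dynamics. Passing tests therefore demonstrate
correctness of the algorithms and the qualitative behaviours (joint-gain
under shared signal and correlated noise, regime difficulty ordering,
survey-size effect) — not field accuracy on real survey data.

## Known limitations

* The learnability check (strong signal, low noise) evaluates forests at
  depth 8: the generating signal is a smooth function of five covariates
  plus an interaction, and 16-leaf depth-4 trees underfit it even as the
  ensemble averages; depth 8 matches the check's purpose (is the generated
  signal recoverable at all?). The survey-application default stays d = 4.
* FGLS residual covariance is estimated in-sample; no out-of-bag variant is
  implemented.
* No spatial autocorrelation modelling; cluster predictions are
  conditionally independent given features.
* Contemporaneous fold assignment is seeded and recorded, but there is no
  spatially blocked cross-validation.
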