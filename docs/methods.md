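# Methods

## The causal model and the two tests

The data model is a cross-sectional survey: per respondent a binary
instrument Z, an ordinal intervention T ∈ {0,…,4}, ordinal outcomes
Y ∈ {1,…,5}, observed categorical confounders X1, and possibly a latent
confounder X2 acting on T and Y only.  The assumed diagram has edges
X1 → {Z, T, Y}, Z → T, X2 → {T, Y}, and a T–Y edge of unknown orientation
(possibly varying across subgroups).

Orientation rests on two d-separation facts.  If T → Y for everyone, then Z
and Y are dependent given X1 (the path Z → T → Y is open) but independent
given (X1, T).  If instead Y → T, then Z ⊥ Y | X1 already, while
conditioning on the collider T *opens* the path Z → T ← Y, so Z and Y are
dependent given (X1, T).  Hence:

* Test B (Z ⊥ Y | X1): rejection necessary for T → Y;
* Test A (Z ⊥ Y | X1, T): rejection necessary for Y → T;
* both rejected: no single orientation fits the whole population —
  heterogeneity; both retained: insufficient evidence.

Rejection is strict (p < α); p = α retains the null.  α defaults to 0.05.

For test efficiency the conditioning sets are the discretized propensity
scores π̄_{X1} and π̄_{X1,T} rather than the raw covariate cells: the score
is a scalar summary of P(Z=1 | ·), so five quantile strata keep the
stratified contingency tables dense enough for the chi-square reference
distribution while still blocking the confounding paths approximately.
Coarsening is a bias/variance trade: exact cell conditioning would give
2·3·4·5 = 120 sparse strata at the default design, where the G² statistic is
visibly anticonservative (expected counts ≈ 3), whereas five estimated-score
strata produce calibrated tests (verified by the null-scenario acceptance
test).  Residual within-stratum score variation can leak a small amount of
dependence; at the default design this stays within the Type-I band tested.

## Test engines

**Conditional MI G-test (default).**  For stratified counts n_szy,
G² = 2 Σ n_szy ln(n_szy n_s / (n_sz n_sy)) = 2·N·MI(Z;Y|S), with 0·ln 0 = 0.
Degrees of freedom are Σ_s (R_s−1)(C_s−1) counting only z/y levels with a
positive marginal within stratum s, so empty levels in sparse strata do not
inflate the reference distribution.  A stratum degenerate on z or y
contributes 0 to both the statistic and the df; a test with total df = 0
raises a degenerate-table error.

**Generalized CMH (cross-check).**  For a binary z and C outcome levels,
Q = U'V⁻U with U the summed deviations of the z=1 row's category counts from
their conditional expectations and V the summed multivariate hypergeometric
covariances; df = C−1; no continuity correction.  The implementation matches
`stats::mantelhaen.test(correct=FALSE)` on reference tables (frozen in the
test suite).  Note the engines target different alternatives — CMH
concentrates power on associations consistent across strata (df = C−1),
G² on any within-stratum association (df ≈ K(C−1)) — so their p-values agree
in decision and co-move with signal but are not numerically coupled under
the null.

**Effect size.**  Cramér's V = √(stat / (N·(min(R,C)−1))) using the
stratified statistic, the global N and the Z×Y dimensions (the conditional
analogue is not standardized in the literature; this is the package's
convention).  Cohen labels use thresholds 0.1/0.3/0.5 scaled by
1/√(min(R,C)−1).

## Propensity estimation and stratification

P(Z=1 | ·) is fitted by maximum-likelihood logistic regression on
dummy-encoded categories; T enters π_{X1,T} as a five-level categorical so
no linearity is imposed on the ordinal exposure; main effects only.  On
non-convergence or quasi-separation (|coef| > 8) the fit falls back to a
small L2 ridge (penalty 1.0 by default).  Scores are clipped strictly inside
(0, 1).

Strata: linearly interpolated empirical quantiles at j/K (default K = 5,
exposed as a parameter), left-closed/right-open bins with a closed top bin;
tied breakpoints collapse.  Strata with fewer than 20 records or with only
one observed Z value are merged into their nearest (smaller) neighbour;
K′ ≤ K is reported.  K = 1 collapses to the marginal (unconditional) test.

## Missing data

Rows missing the outcome under study or T are excluded from the causal tests
(Test A conditions on T, so a missing T cannot be conditioned on);
descriptive cross-tabs may retain a missing category.  Missing categorical
confounders are imputed by chained equations: each incomplete confounder is
modelled by multinomial logistic regression on the other confounders plus Z,
T and the outcomes (missing values of those predictors enter as an explicit
category), cycled for 10 iterations, with imputed categories *drawn* from
the fitted class probabilities.  Z, T and outcomes are never imputed.
Defaults: m = 100 completed datasets, seeds base_seed + 1..m.

P-values are pooled across imputations by the **median** (default).  The
median is valid without normality assumptions and robust to single unstable
imputations; `mean` and `licht_rubin` (probit transform, Rubin's rules on
the z-scale) are available by configuration since the pooling rule for
imputed p-values is not uniquely standardized.  Effect sizes pool as the
median Cramér's V.  Imputations whose tests are degenerate are dropped with
a warning; losing more than half aborts the analysis.

## Subgroup descent

A heterogeneous verdict automatically reruns the *entire* pipeline
(propensity fits, stratification, both tests, pooling) within each level of
the pre-specified subgroup variables; it can also be forced.  Levels with
fewer than 200 records are flagged underpowered; empty or untestable levels
are reported, never raised.  The framework tests for the *existence* of
heterogeneous directions within the given grouping; it does not search for
the variables that drive heterogeneity.

## The synthetic generator

`ScenarioSpec` fixes a complete structural model sampled in causal order:
X1 categorical (defaults: 2/3/4-level variables with marginals
0.58/0.42, 0.5/0.3/0.2, 0.1/0.15/0.3/0.45, echoing gender/education/age
structure; centred level-effect patterns scaled by
`confounding_strength_x1` = 0.5); X2 ~ N(0,1);
Z ~ Bernoulli(logistic(0.5 + X1 effects)) (≈62% Z=1, matching the observed
savvy share); T and Y from ordered-threshold models with logistic noise.
T's cutpoints (0.20, 0.80, 1.66, 2.44) put the baseline mass at
(.55, .14, .15, .08, .08) — the heavy non-user skew that stresses the
stratification code; Y's cutpoints (−2.94, −1.73, −0.62, 0.62) give the
confident-response skew (.05, .10, .20, .35, .30) typical of Likert
self-efficacy items.  The causal edge enters centred — effect·(T−2) into Y
(forward) or effect·(Y−3) into T (reverse) — so `effect_strength` is
symmetric between directions.  Defaults `iv_strength` = 1.2 and
`effect_strength` = 0.8 define the "strong" presets: a clearly relevant
instrument and a causal effect comparable to the confounding, the regime the
method is designed for.  The mixture scenario ties the mechanism to an
*observed* group column (`grp`), so subgroup recovery is well defined; the
homogeneous scenarios emit an uninformative 50/50 `grp` for negative
controls.  MAR missingness uses P(miss) = logistic(a + 0.5·Z + 0.3·(Y−3))
with the intercept bisected per dataset to hit the target rate, making
missingness depend on observed quantities (MAR, not MCAR).

Presets (fixed, documented): `forward_strong`, `reverse_strong` (n = 4000),
`null` (n = 2000, effect 0), `mixture_even` (n = 6000, fraction 0.5),
`forward_confounded` (latent strength 0.7).

What the generator does *not* emulate: complex survey sampling and weights,
item-specific response styles, multi-outcome correlation structure, and
non-logistic noise.  Passing tests therefore demonstrate the pipeline's
statistical behaviour under a faithful instrumented SCM, not performance on
any particular real survey.

## Numerical and design choices

* Zero cells contribute 0 to G²; df counts positive-marginal levels only.
* Propensity scores clipped to (1e−12, 1−1e−12); separation threshold 8 on
  |coef| before the ridge fallback.
* Quantile convention: `numpy.quantile` linear interpolation.
* Boundary p = α counts as non-rejection.
* Stand-in conditioning with K = 1 reduces Test B to the marginal Z–Y test
  (used by the reduction tests).
* The reference cross-tabulation bundled in `ivdirect.datasets` carries the
  published counts for 2,579 cancer-history respondents; its chi-square test
  (respondents only) and the two non-user percentages are recomputed, not
  stored, by `scripts/acceptance.py`.

## Problem sizes used by the acceptance battery

Null calibration: 300 replicates at n = 2000 (script) / 500 (test suite);
direction recovery: 150/200 replicates at n = 4000; heterogeneity: 80/100
replicates at n = 6000; imputation stability: 20/50 replicates with m = 20,
10 chained-equation iterations.  These sizes give Monte-Carlo standard
errors of a few percentage points on the reported rates while keeping the
battery to minutes on a single CPU.

## Known limitations

* With a latent T–Y confounder X2, conditioning on T (Test A) opens the
  collider path Z → T ← X2 → Y, so Test A can reject under pure forward
  causation; strong latent confounding therefore pushes verdicts towards
  "heterogeneous".  The `forward_confounded` preset exposes this behaviour;
  the framework does not resolve it.
* Coarse score strata leak a small amount of residual dependence; with many
  confounders or very strong effects the Type-I behaviour of Test A should
  be re-checked by simulation at the user's design.
* The G-test relies on the chi-square approximation; with very sparse strata
  (expected counts well below 5) it is anticonservative, which is why
  stratification, minimum stratum sizes and level merging exist.
* Verdicts are about direction only; the framework estimates no causal
  effect magnitudes.
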