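# Methods

This note documents the statistical content of `fvgdr`: what is modelled,
which conventions were chosen where several were defensible, and what the
synthetic-data generator does and does not emulate.

## Scoring

Each assessment method is reduced to six binary indicators per
respondent-day over the GDR fruit-and-vegetable groups (vitamin A-rich
vegetables, dark green leafy vegetables, other vegetables, vitamin A-rich
fruits, citrus, other fruits). Questionnaire answers map one-to-one onto
indicators. Recall indicators aggregate item-level gram records through a
country-specific item→group mapping; items absent from the mapping are
treated as non-fruit/vegetable and excluded (their count is logged).

Three recall scoring modes are supported:

* **threshold** (default): a group counts when at least one of its items
  reaches `min_grams` (15 g, inclusive). The 15 g rule is applied per
  food item, after summing duplicate rows of the same item within a
  respondent-day — a deliberate robustness choice, since data-entry
  granularity (one row per dish vs. per helping) should not move an item
  across the threshold. An `aggregate="group"` option applies the rule to
  the group-day total instead, for sensitivity analysis; whether the
  per-item or per-group convention is "correct" is underdetermined in the
  field, so both are available and the per-item one is the pinned default.
* **all_quantities**: any positive amount counts.
* **sentinel_only**: as threshold, restricted to sentinel items (the
  foods a list-based questionnaire explicitly asks about).

The eligible item sets are nested (sentinel_only ⊆ threshold ⊆
all_quantities), so scores are monotone across modes; the test suite pins
this. Total F&V intake (g/day) sums *all* mapped items with no gram
filter — the filter exists only to align recall indicators with what a
yes/no questionnaire can plausibly detect, and applying it to gram totals
would bias intake downward.

The FV-GDR score is the sum of the six flags (0–6). `meets_cutoff`
implements the score ≥ k adherence rule.

## Agreement statistics

Per group, matched respondent-days are cross-tabulated as a (neither
positive), b (questionnaire-only, type I / false positive), c
(recall-only, type II / false negative), d (both positive). Conventions:

* percentage agreement = ((a+d)/n)·100;
* misreporting percentages are over **all** n observations (b/n, c/n),
  not over the margins — under this convention agreement + FP% + FN% =
  100 exactly, which makes the three numbers mutually auditable;
* sensitivity d/(c+d) and specificity a/(a+b) treat the recall as the
  reference; a zero denominator yields NaN ("not available") rather than
  an arbitrary 0 or 1;
* prevalence differences are questionnaire − recall in percentage
  points, tested with a linear probability model on the stacked
  indicator with a respondent random intercept (REML), which absorbs the
  dependence among the up-to-four observations each respondent
  contributes. The exact form of such a test is genuinely open (logistic
  GLMM, GEE and the LPM all defensible); the LPM was chosen because its
  fixed effect *is* the prevalence difference and it is numerically
  robust at desk scale. Degenerate all-constant indicators return NaN.
  A difference is flagged *meaningful* only when p < α (0.05) and
  |difference| > 10 pp.

## Score-level inference

**Wilcoxon.** Paired signed-rank on per-observation score differences;
zero differences discarded; exact null for ≤ 25 informative pairs without
ties, normal approximation with tie correction otherwise. All-zero
differences return statistic 0, p = 1 by convention. The test treats
observations as exchangeable pairs and ignores the day-within-respondent
clustering — a known simplification shared by common practice.

**Standardized mixed-model slope (β_st).** Both variables are
z-standardized over all observations (sample SD, ddof = 1); then
y\* = β·x\* + u_respondent + ε is fitted by REML with a Wald 95% CI on β.
With singleton clusters the marginal covariance is proportional to the
identity, so the estimate equals the standardized OLS slope exactly (a
pinned oracle); with a perfect linear relationship the residual variance
is zero and the fit degenerates, so that case short-circuits to β = ±1
with a collapsed interval. The fit is cross-checked against R's
`lme4::lmer` in the test suite. Wald (not profile) intervals are used:
they match the usual "95% CI" reporting and are cheap; coverage is
verified by a parameter-recovery simulation.

**Dependent overlapping correlations.** r12 (intake vs. recall score),
r13 (intake vs. questionnaire score) and r23 (between scores) are plain
product-moment correlations over all observations, clustering ignored —
this matches how such comparisons are conventionally run, and the
mixed-model β_st values are reported alongside precisely because they
handle clustering. The comparison implements:

* *Hittner z*: Dunn & Clark's statistic on the Fisher transforms of r12
  and r13, with the covariance term evaluated at the back-transformed
  mean of the two Fisher transforms;
* *Zou interval* for r12 − r13: individual Fisher-interval limits
  combined with the estimated correlation between the two sample
  correlations.

When r12 = r13 exactly (e.g. error-free synthetic data, where r23 = 1
makes the covariance term degenerate) z is defined as 0 with p = 1.
|r12| = 1 or |r13| = 1 is a hard error (Fisher transform undefined);
n < 10 likewise. Calibration (type-I error in [0.03, 0.07] at n = 300,
Zou coverage 93–97%) and antisymmetry under swapping r12/r13 are enforced
by tests, with a nonparametric-bootstrap power cross-check.

**Cut-off analysis.** Observations are labelled by intake ≥ 400 g/day
(configurable); half-integer cut-offs −0.5 … 6.5 are swept and the
Youden-J maximizer returned, ties resolving to the smallest cut-off.
Youden J is an implementation decision for "optimal" — it weighs
sensitivity and specificity equally and produces half-integer optima by
construction. The proportions of observations at/above an integer
cut-off are reported per method because population-level adherence
monitoring compares exactly those shares.

## Synthetic-data generator

Per respondent, a propensity random effect u ~ N(0, σ_w) on the logit
scale is shared across the two days; latent consumption of group g on a
day is Bernoulli(logistic(logit(π_g) + u)). σ_w defaults to 0.8 — enough
to make ignoring clustering visibly anticonservative, typical of repeated
dietary indicators. Each consumed group-day yields 1–3 items (uniform);
each item is a sentinel item with probability `sentinel_coverage[g]`, and
its gram amount is lognormal(μ_g, σ_g) (defaults ln 70 g, 0.5 —
right-skewed, realistic portion scale) **floored at 15 g**, unless the
item is flagged small-portion (probability `small_portion_prob[g]`), in
which case it is drawn uniform on (2, 14) g. The floor makes "regular"
portions deterministically eligible under the 15 g rule, so the
error-free configuration satisfies an exact identity: questionnaire
answers equal threshold-mode recall indicators on every respondent-day.
Without it, the lognormal left tail would leak sub-threshold portions at
a rate confounded with the explicit small-portion mechanism. Amounts are
rounded to 0.1 g (field scales read to one decimal). A staple row
("rice", unmapped) is added to every recall day so the pipeline's
unmapped-item path is always exercised and every respondent-day exists
in the recall table.

The questionnaire answer for a group is the latent flag flipped 0→1 with
probability φ_g (false positive) and 1→0 with probability ν_g (false
negative) — error is injected at the group level because a list-based
questionnaire only observes group-level yes/no. The recall table is
recorded faithfully; the truth ledger stores latent flags and true gram
totals.

Three presets encode recognisable validation-study regimes:
`no_error` (identity baseline); `hanoi_like` (high-variety groups —
other vegetables/other fruits — under-reported by the questionnaire:
ν ≈ 0.3, low sentinel coverage, mild false positives on leafy greens and
citrus); `ibadan_like` (vitamin A-rich vegetables habitually eaten as
sub-15 g sauce ingredients: prevalence 0.95, small-portion probability
0.6, φ = 0.3). Preset parameter values are scenario descriptors chosen to
produce the qualitative error structure named, not estimates of any real
population.

What the generator does **not** emulate: day-of-week and seasonal
effects, correlated errors between the two methods (both instruments'
errors are independent given the latent flags, whereas real same-
interview assessments share memory errors), recipe disaggregation,
intra-item portion-size reporting error, and any covariate structure
(age, sex). Passing tests therefore demonstrate the *statistical
machinery* is correct and well calibrated, not that any particular field
population behaves like a preset.

## Numerical choices and problem sizes

* Mixed models: statsmodels `MixedLM`, REML, default BFGS optimizer with
  a Powell fallback (the L-BFGS path can hit singular score matrices on
  boundary-variance data); convergence failure after both attempts is a
  hard error carrying the problem size.
* Covariance-term clamping: the Hittner denominator 2 − 2c is floored at
  1e-12 to keep r23 → 1 edge cases finite.
* Reports round percentages to one decimal and keep raw 2×2 counts, so
  every printed rate can be re-derived by hand; JSON output is sorted and
  NaN-free (NaN → null) to make reruns byte-comparable.
* Test problem sizes (600 respondents × 2 days for end-to-end runs;
  5,000 respondents for closed-form misreporting recovery; 50 replicates
  for the attenuation ordering; 1,000 replicates of n = 300 for test
  calibration; 100 replicates of 500 × 2 for CI coverage) were chosen as
  the smallest scales at which the Monte-Carlo bands in the corresponding
  checks are decisive.

## Known limitations

* The prevalence-difference p-value comes from a linear probability
  model; with prevalences very near 0 or 1 its Wald test is approximate.
* Sensitivity/specificity treat the recall as an error-free reference;
  in reality recalls under-report episodically consumed foods, which
  inflates apparent questionnaire false positives. The generator can
  mimic the consequence (via small portions) but not correlated recall
  error itself.
* The Youden-J cut-off is an equal-weights choice; applications that
  value sensitivity over specificity (or the reverse) should sweep the
  reported J components instead of taking the optimum as given.
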