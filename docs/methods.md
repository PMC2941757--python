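# Methods

## Model structure

The simulator follows individual entities in discrete weekly time over
a 208-week horizon. Weeks 1–104 are a run-in ending at a baseline
interview; week 208 is the follow-up interview, matching a biennial
survey design. Each entity has a fixed attribute profile — one of five
age groups (12–18 reference, 19–25, 26–45, 46–65, 66+) crossed with
binary pain, smoking and childhood-stressor indicators, 40 profiles in
all — and receives exactly one new episode onset, uniform on weeks
1–104. There are no events before onset; the entity's prior interview
(week 0) is therefore negative by construction, emulating an analysis
file restricted to new-onset episodes.

State transitions are evaluated at week end. A depressed week ends with
a Bernoulli recovery draw at

p_rec(t) = 1 − exp(−exp(α + β_age + β_logtime · ln t)),

the inverse complementary-log-log link, where t is the weeks-depressed
counter. A recovered week ends with a Bernoulli recurrence draw at the
profile's constant inverse-logit probability. A recovery and a
recurrence can never occur in the same week (the simplest reading of a
weekly event loop); an entity that recovers at the end of week w is
first at risk of recurrence at the end of week w+1. Episodes ongoing
at the horizon are recorded as censored, not discarded.

### The episode clock

The hazard is first evaluated at the end of the first depressed week,
with ln(1) = 0, so every episode lasts at least one week and log-of-zero
never arises. The counter driving the log-time term is **cumulative
across episodes** within an entity by default: the survey's
weeks-depressed item does not distinguish weeks within one episode from
weeks across episodes, and the model's counter mirrors that item. The
alternative reading — restart the clock at each recurrence — is
implemented behind `reset_clock_on_recurrence` (default off). "Log"
is the natural logarithm; the base is a modelling choice documented
here because either base can be absorbed into β_logtime.

### The recurrence equation

The recurrence linear predictor is a sum over a **closed** set of 31
published rows: an intercept, 7 main effects, and 23 age-by-risk-factor
cross-product terms. A row contributes iff every factor in its label is
active in the profile. Attribute combinations without a published row
(e.g. plain pain×stressor with no age factor) are structural zeros:
they contribute nothing and are deliberately not addressable as
coefficients — looking one up raises an error rather than silently
returning 0. Coefficients may be −∞ as an explicit "never recur"
sentinel.

## Observation layer

Each interview asks about the 52 weeks up to and including the
interview week ("the year preceding the interview"). Positivity
requires at least `min_weeks_positive` depressed weeks in that window;
the default is 1, while the underlying diagnostic instrument nominally
requires a two-week symptomatic spell, so the stricter reading is one
config value away. The weeks-depressed item is capped at 52 and
collapsed into {1–6, 7–12, 13–25, 26–52}: the two middle categories are
fixed by the survey analysis, the outer bounds complete the partition
and are configurable. Records not baseline-positive are flagged
excluded; per-profile summaries (follow-up positivity, category
proportions) are computed over included records only, and empty
profiles are flagged and skipped by the calibration objective.

## Survey-side models

Consecutive positivity is modelled by binary logistic regression
(terms: age 26–45, smoker, childhood stressor, pain) and the weeks
categories by a proportional-odds model (age dummies only), both fit by
statsmodels maximum likelihood with Wald intervals, matching the
printed confidence-interval style. Separation and non-convergence
raise explicit errors. The ordinal convention is
P(Y ≤ j | x) = expit(κ_j − xβ), so positive coefficients shift mass
toward longer durations.

Brant's test is implemented from its definition: fit the J−1 cumulative
binary logits separately, assemble the joint covariance of the slope
estimates from the fitted-probability cross-products, and form Wald
statistics for equality of each covariate's coefficients across
equations. The omnibus degrees of freedom are (J−2)·K — 8 for four
categories and four covariates. Published applications sometimes quote
other df conventions (a reported value of 12 exists for the motivating
analysis); this package documents and uses (J−2)·K and does not force
agreement.

## Synthetic respondents

The generator draws covariates independently at configurable
prevalences (defaults: age 0.15/0.15/0.35/0.25/0.10; pain 0.10; smoker
0.30; stressor 0.30 — fabricated, since true prevalences are
unpublished), a consecutive-positivity outcome from the logistic model
(default truth: the published odds ratios 1.5/1.5/2.0/1.6 with
intercept −2.0), and a weeks category from the proportional-odds law
(default truth: the published age coefficients with cut-points
0.0/0.8/1.6, chosen to put roughly half of reference-group episodes in
the 1–6-week category, consistent with mostly-short episodes). Default
sample size is 1,857 — the size of the consecutive-positivity analysis
file — with larger n used where tests need precision. The generator
emulates none of the survey's sampling design, weights, attrition or
recall error; passing tests therefore validate the estimation chain,
not robustness to those real-data features.

## Calibration

The objective simulates a cohort, observes it, and sums squared
residuals over two equally weighted blocks: 40 per-profile consecutive-
positivity proportions and 5 per-age-group 4-category distributions
(equal weights are a choice; the block weighting is exposed through the
target structure, which accepts either block alone). Common random
numbers — the uniform stream depends only on (seed, profile index,
entity index), never on parameters — make the objective deterministic
given the seed, so self-generated targets are attainable exactly and
the minimum is genuinely zero there.

The search is bounded Nelder-Mead with seeded restarts (box centre
first, then uniform draws), replacing the proprietary optimizer used in
the original workflow with standard open machinery. Supported practice
is low-dimensional calibration (≤6 free coefficients, the rest pinned):
the full 31-term recurrence equation is not identifiable from 45 target
numbers, which is precisely the excess-complexity problem the model
family is known for. With positivity targets alone, recovery and
recurrence trade off (persistence vs recurrence both produce
consecutive positivity); the test suite demonstrates that adding the
category block shrinks the across-restart spread of recovered recovery
coefficients.

## Numerical and scale choices

- Weekly probabilities use `-expm1(-exp(x))` and `scipy.special.expit`
  for accuracy in the tails; NaN inputs raise, ±∞ map to the 0/1
  sentinels.
- Simulation is vectorised across all entities with one 208-step loop;
  cohorts of a few hundred thousand person-weeks simulate in well under
  a second, and one calibration objective evaluation with 40×100–150
  entities takes ~0.1–0.2 s.
- Test and default problem sizes are chosen for desk-scale runs: 400
  replicates at n = 1,000 for the Brant type-I suite, 100–150 entities
  per profile and budgets of a few hundred evaluations for calibration
  experiments, 20,000 entities per age group for duration refits, 10⁶
  person-weeks per profile for recurrence contrasts, 50,000 respondents
  for regression recovery. Empirical checks use 3-standard-error Monte
  Carlo bands.
- The small-horizon simulator law is verified against exact path
  enumeration (an independent recursive oracle), and simulated survival
  against the closed-form product ∏(1 − h_k).

## Known limitations

- No seasonality of onset (kept only as the uniform-onset assumption),
  no mortality, treatment, severity states, or recall-error model.
- The weeks-depressed item is assumed to cap at exactly 52.
- Empirical recurrence contrasts involving the 66+ group at 10⁶
  person-weeks rest on a few dozen events (weekly probability ≈ 2×10⁻⁵),
  so their Monte Carlo standard error is ~0.2 on the log-odds scale;
  difference-in-differences estimates of that group's interactions
  inherit it.
- Calibration identifiability beyond low-dimensional subsets is poor by
  construction of the problem, not by deficiency of the optimizer.
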