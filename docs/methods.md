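# Methods

## Data model

A `CategoricalPanel` is a subjects × waves grid of category codes under a
`CategoryScheme` (2–8 ordered, unique levels; for readable lasagne plots at
most four substantive levels are recommended).  Wave indices are the literal
survey numbers (e.g. 2…5), never re-indexed to zero: the marginal-trend
model fits the survey number directly, so intercepts and slopes keep their
natural interpretation.  Waves must be equally spaced for the models to be
meaningful; `CategoricalPanel.regular_spacing` exposes the check but the
package does not attempt to model irregular designs.

Missing cells hold a reserved sentinel (`MISSING`), never a string;
comparing it to a label with `==` raises `TypeError` so that missingness
cannot silently compare false.  Reading delimited text matches category
strings exactly by default, with an opt-in case/whitespace-normalising
flag — silent fuzzy matching is a data-corruption hazard.

A scheme may declare a *monotone absorbing source*: a level that, once
left, cannot be re-entered (the canonical example is "never smoker").
`reclassify_monotone` repairs observed violations by relabelling each
offending cell — every source-level cell preceded at any earlier wave by a
different non-missing level — to a caller-chosen level (e.g. "ex").  Cells
are relabelled independently rather than propagating forward, which is the
weaker of the two defensible readings of the repair and is overridable by
the caller simply by re-running with different data; missing intermediate
waves are ignored when detecting prior "ever" status.

## Nominal logistic regression

The core fitter maximises the multinomial log-likelihood
`Σᵢ wᵢ log π_{yᵢ}(xᵢ)` with `π` a soft-max over the *permitted* levels of
each row.  Structural zeros are implemented by masking levels out of the
per-row normalisation — equivalent to coefficients fixed at −∞ — so
impossible outcomes carry probability exactly zero, not a small number.

Optimisation is Newton–Raphson with the analytic score and observed
information, step-halving on any likelihood decrease (so the likelihood is
monotone over iterations), and an escalating ridge (relative diagonal
inflation) if the information is singular at an iterate.  Convergence is
declared when the maximum absolute score drops below `tol` (default 1e-6);
iterates whose linear predictors exceed 30 in absolute value trigger a
complete-separation warning naming the driving predictor.  Starting values
are zero; the likelihood is concave so the optimum is global.

Identifiability under structural zeros: when an outcome level is masked for
part of the sample, a predictor can be constant on the rows where that
outcome is possible (e.g. every ever-smoking indicator is identically zero
on the all-"never"-history rows, the only rows where a "never" outcome is
possible).  Such coefficients are not identified and are fixed
(structurally) at zero; `fit_transition` detects them automatically and
`fit` accepts explicit `(outcome, column)` constraints.  Constrained
entries appear with RRR 1, SE 0 and a `constrained` flag in the summary
table, and carry zero rows/columns in both covariance matrices.

Two covariance matrices are always computed: the inverse observed
information, and the cluster-robust sandwich `A⁻¹BA⁻¹` with `B` the sum
over clusters of outer products of cluster-summed scores.  Clustering is on
subject wherever multiple rows per subject exist (pooled transition fits,
marginal fits); with one row per cluster the sandwich reduces to HC0.
Wald intervals use normal quantiles with no degrees-of-freedom correction,
appropriate at cohort sample sizes.

Diagnostics:

- **McFadden pseudo-R²** `1 − ℓ/ℓ₀`, with the null an intercepts-only fit
  on the same rows and structural-zero mask.
- **Percentage log-likelihood gains**: each model-building step's gain
  expressed as a percentage of |ℓ₀|.  The denominator is fixed at the null
  for all steps, so the first entry is the pseudo-R² in percent and later
  entries are increments on the same scale.
- **Proportion correct**: share of rows whose observed level is the modal
  fitted probability among permitted levels; ties break to the lowest level
  code (logged).
- **VIF** per non-constant design column, `1/(1−R²)` from a least-squares
  regression of the column on all others plus an intercept.

## Marginal models

`fit_marginal_trend` stacks one row per observed subject-wave and fits wave
either numerically (a log-linear trend per outcome level — the default, as
cohort categorical trends are typically near-linear on the log-RRR scale)
or categorically (the saturated marginal model, whose fitted marginals
equal the observed ones exactly; the numeric model is nested within it).
Subjects with partial data contribute the waves they have unless a
complete-case restriction was applied upstream.  Goodness of fit is the
absolute difference between model-predicted and observed marginal
probabilities per wave and level.

## Transition models

`build_lag_design` expands a panel into one row per subject-wave with a
complete lag window: intercept, per-level indicators at each requested lag
(baseline = the lag reference level, by default the outcome reference), and
optional joint indicators for specific level sequences.  Two codings are
offered for joint indicators.  *Additive* (default) keeps the single-lag
indicators untouched, so the joint effect multiplies onto them;
*mutually exclusive* zeroes the constituent single-lag indicators whenever
the joint fires, so each coefficient reads as an exclusive contrast
("ex last wave but not the wave before").  The two codings span the same
column space and give identical fitted probabilities; only the coefficient
parameterisation differs.

The permitted-outcome mask is rule-driven from the scheme's absorbing
source (plus any custom `(outcome, history-predicate)` rules), applied to
each subject's full earlier observed history rather than only the lag
window — a subject who smoked three waves ago cannot be a never smoker now
even if the model only uses one lag.

Fits can target a single wave (default: the last, which mirrors the usual
"predict the final survey" presentation) or pool all eligible waves into
one fit with subject-clustered variances.

**Transition probabilities with delta-method intervals.**  For a covariate
pattern (history) the probabilities are the masked soft-max of the fitted
linear predictors.  The SE of each probability propagates the coefficient
covariance V through the gradient `∂π_m/∂β_j = π_m(1{m=j} − π_j)x`,
`se = √(gᵀVg)`.  Intervals are symmetric on the probability scale and
truncated to [0,1] by default; a logit-scale option transforms a symmetric
log-odds interval instead, which keeps intervals inside (0,1) and allows
the asymmetry that near-boundary probabilities (99% vs 98.8–99.3%) call
for.  Structurally excluded outcomes report probability 0 with SE 0 — a
fact, not an estimate.

**Lag selection.**  `select_lags` fits depths 1…max on a common row set
(subjects observed over the deepest window, so log-likelihoods are nested
and comparable) and tabulates the maximum VIF across indicator columns and
the incremental percentage log-likelihood gain.  The recommended depth is
the deepest consecutive depth with max VIF < 5 and gain ≥ 1 percentage
point; depth 1 is always admissible.  Percentage gains are preferred to
absolute likelihood changes because they read directly as predictability
for individuals.  The default thresholds are conventional round numbers —
VIF 5 is the common moderate-collinearity cutoff and 1% of the null
log-likelihood is a gain too small to change qualitative conclusions —
and both are caller-adjustable.

**Probability trees.**  Subjects with the root level at the root wave and
complete follow-up are partitioned recursively by level at each later
wave; each node holds the path count and the conditional probability given
its parent (children sum to one, counts conserve).  Trees are rendered with
leaves in level order and internal nodes centred on their children.

## Lasagne-plot geometry

`compute_flow_layout` groups subjects by full trajectory; each wave's bar
is partitioned primarily by current level in scheme order, and within a
level by trajectory-group order, so colour bands are contiguous and
transitions traceable between adjacent bars.  Within-bar ordering is not
canonical; the default sorts trajectories lexicographically by level
sequence, and an alternative keeps baseline (first-wave) cohorts contiguous
inside each colour block.  Crossing-minimising orderings are out of scope.
The layout obeys exact conservation laws — band heights at each wave sum to
the subject count; flows out of and into each band equal its height — which
are property-tested over random panels; pixel output is never compared.

Rendering uses the Okabe–Ito colour-blind-safe palette keyed by level
order, grey for a "missing" level, and refuses schemes with more than 8
levels (four substantive categories at most are recommended for
interpretability; collapse levels first).

## Synthetic panels

`MarkovPanelSpec`/`simulate_panel` generate trajectories from a first- or
second-order Markov chain: initial distribution over levels, row-stochastic
transition matrix (or J×J×J array; the second wave of an order-2 chain uses
the order-1 marginalisation of the array under the initial distribution),
optional absorbing-source validation so monotone panels are monotone by
construction, and missingness applied after the complete trajectory is
drawn (missing-at-random given the current level), so complete-case and
missing-as-category analyses exercise the same draw.  Defaults in tests
mirror a cohort of order 10³–10⁴ subjects over four waves with three-level
outcomes and strongly persistent chains, which is the regime the models
target.

What the generator deliberately does not emulate: covariate-driven
heterogeneity between subjects, time-inhomogeneous transition matrices,
informative (outcome-dependent-on-future) missingness, and measurement
error in the recorded categories.  Passing parameter-recovery tests on
these panels therefore demonstrates correctness of the estimators under
the models' own assumptions, not robustness to their violation.

`spec_from_fit` converts a fitted first-order transition model back into a
simulation spec (structural zeros preserved as exact zeros), closing the
simulate → fit → simulate loop used in round-trip tests.

## Validation strategy and problem sizes

The estimators are validated against independent routes rather than against
themselves: statsmodels' multinomial logit and an iteratively refined
brute-force grid search for the MLE; cluster bootstrap and parametric
Monte-Carlo simulation for robust and delta-method SEs; direct
cross-tabulation for saturated fits; hand-enumerated fixtures for designs,
trees and layouts.  Repeated-simulation checks use 100 replicates of
800–1,000-subject, four-wave panels and require ≥90% empirical coverage of
nominal 95% intervals; Monte-Carlo SE comparisons use 2,000 parameter
draws.  These sizes give the tests stable verdicts while keeping the whole
suite in the tens of seconds.

## Known limitations

- Ordinal structure is ignored by design: nominal models apply to ordered
  and unordered categories alike, at some efficiency cost for ordinal ones.
- No mixed/random-effects models; within-subject correlation is handled
  only through robust variances.
- Irregular wave spacing is not supported, and continuous variables must be
  categorised first.
- Separation (deterministic transitions) yields finite-precision estimates
  with a warning rather than exact 0/1 probabilities; fitted probabilities
  are still accurate to ~1e-9.
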