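# Methods

## Task model

The simulator reproduces the probabilistic classification task exactly
as administered: 160 scored trials in 4 blocks; within each block every
stimulus appears exactly 10 times, 8 of them carrying its majority
category and 2 the minority category, and the 40 trials are then
shuffled uniformly.  Composition is exact per block, not i.i.d.
Bernoulli(0.8) sampling per trial, because the session is defined by its
block composition; this also removes a source of between-session
variance that the analysis does not model.  Instruction screens and the
two unscored practice trials are not simulated.  Stimulus identity is
abstract (S1–S4); the random assignment of pictures to roles is
cosmetic and omitted.  The point tally starts at 500, moves by ±25, and
has no floor.

Feedback contract: reward trials pay +25 on a *correct* classification
(the category sampled on that trial) and give nothing otherwise;
punishment trials take −25 on an incorrect classification and give
nothing otherwise.  *Optimal* responding — the quantity analysed — is
defined against the majority category and is independent of the sampled
category, so a response can be optimal yet incorrect on a minority-
sample trial.

## Choice model

Softmax with an "inverse gain" β acting as a temperature:
Pr(A) = exp(Q_A/β) / (exp(Q_A/β) + exp(Q_B/β)).  The source equation is
only described verbally, so the convention is fixed by the stated
behavior — low β ⇒ exploit the higher expectancy, high β ⇒ random — and
by the stated range β ∈ [0, 1], whose lower endpoint only makes sense
when β divides.  β = 0 is evaluated as the greedy limit (probability 1
for the strictly larger expectancy, 0.5 on ties).  In likelihood mode a
greedy parameter point therefore scores −∞ unless the session is
perfectly consistent with greedy choice; no probability flooring is
applied anywhere else, since flooring would silently move the MLE.

Numerics: both response probabilities are computed through their own
logistic, `expit(±d/β)` with d the expectancy difference.  Computing the
unchosen side as `1 − expit(d/β)` underflows to exactly 0 once d/β ≈ 37,
which would fabricate −∞ log-likelihoods at small β; the symmetric form
keeps the probability denormal-positive down to d/β ≈ 745, far beyond
anything reachable with |Q| ≤ 1.

Updates touch only the chosen (response, stimulus) entry, with the gain
learning rate for positive prediction errors and the loss rate for
negative ones; the prediction error is always computed from the response
actually emitted (the participant's in likelihood mode, the sampled one
in generative mode).  Expectancies therefore stay inside
[min(R⁻, R0, 0), max(R⁺, R0, 0)] for any parameter values — a property
test asserts this on random sessions.

## Estimation

The estimator is an exhaustive grid search: 21 values each for α_G, α_L,
β (step 0.05) and 21 for R0 (step 0.1), 194,481 combinations.  No
continuous optimiser refines the result; the grid *is* the estimator.
The vectorized evaluator exploits the fact that the expectancy
trajectory depends on (α_G, α_L, R0) but not on β: one replay per
(α_G, α_L, R0) combination records the chosen-minus-unchosen expectancy
difference on every trial, and each β then scores those differences
through a stable softplus.  The evaluator must agree with the readable
scalar replay to 1e−9 per session (tested), so the optimisation cannot
drift from the definition.

Ties (flat likelihood regions, e.g. any session scored with both
learning rates at 0) are broken deterministically toward the first point
in ascending lexicographic order (α_G, α_L, β, R0), and the tie count is
reported.  Tie detection compares exact floats; this is reliable here
because tied likelihoods arise from identical arithmetic, and it is
deliberately not tolerance-based, which would conflate near-ties with
ties.

## Behavioral scoring

Percent optimal is computed separately over the 80 reward and 80
punishment trials (and per block of 40).  The solver threshold is
inclusive — at least 65%, i.e. ≥ 52 of 80, the smallest count for which
the exact two-tailed binomial test against chance beats p < 0.01; the
package derives 52 from the test rather than hard-coding it.  The
below-chance flag on reward trials is strict (< 35%, i.e. ≤ 27 of 80):
"at or below 35%" never occurred on punishment trials in the reference
data, so nothing hinges on the boundary, and the strict reading mirrors
"less than 35%".  Percentages are exported rounded to one decimal but
all comparisons use exact counts.

## Group statistics

Chi-square tests use expected counts from the margins, with the Yates
continuity correction (|O−E| shrunk by 0.5, floored at 0) for 2×2
tables; the computation is delegated to `scipy.stats.chi2_contingency`,
which implements exactly this definition, and is cross-checked against
the textbook formula in the tests.  The exact binomial test doubles the
smaller tail (equivalent, at p₀ = 0.5, to summing outcomes at least as
extreme).  Two-sample t-tests are computable directly from printed group
summaries (mean, SD, n), pooled or Welch–Satterthwaite.  Correlations
are Pearson or Spearman with two-sided p.  Mixed-model ANOVA machinery
is out of scope: those analyses need the unavailable raw cohort and are
routine.

## Synthetic cohorts

The generator's job is to produce cohorts with the statistical structure
the analysis assumes, with ground truth retained.  Defaults: two groups
of 39 ("control") and 48 ("PTSS") agents.  α_G, α_L and β are shared
across groups — the reference analysis found no group differences in
them — and drawn from normals truncated to [0, 1] around the cohort-wide
estimates (α_G: 0.27, SD 0.32; α_L: 0.23, SD 0.34; β: 0.34, SD 0.27).
R0 is truncated-normal on [−1, 1] centred at +0.5 (control) versus 0.0
(PTSS).  The 0.2 spread of R0 is this package's choice — only the group
centres and a cohort-wide SD are reported upstream — and is configurable.
Medication, combat-history and behavioral-inhibition labels are sampled
at the reported group frequencies purely to exercise the contingency
statistics; they have no behavioral effect.

What the generator does *not* emulate: within-participant
non-stationarity (fatigue, strategy switches), perseveration beyond what
the four parameters produce, response omissions, reaction times, and any
genuine coupling between covariates and behavior.  Passing direction
tests on these cohorts therefore shows that the pipeline recovers the
structure it was told to generate — a necessary internal-consistency
check, not evidence about real populations.

A note on an expected asymmetry: with only R0 differing between groups,
the model predicts the control preset is *worse* on reward trials and
*better* on punishment trials.  Empirically the reward effect was the
reported one and the punishment difference was absent.  In simulation the
punishment-trial gap is real but consistently smaller than the
reward-trial gap, and the directional tests assert exactly that ordering
rather than a null punishment difference, which the model family cannot
produce with these presets.

## Problem sizes and seeds

Choices made for the standard validation runs: direction properties are
averaged over 3 replicate 87-agent cohorts (single cohorts occasionally
invert the gap ordering by sampling noise); the fitted-R0 group
comparison uses one full cohort on the full grid; recovery uses 200
agents at 160 trials for the rank-correlation check and 12 paired agents
(same true parameters) at 160 versus 1,600 trials for the
error-shrinkage check.  Every run's randomness descends from a single
seed; per-agent seeds are drawn from the master generator, so cohorts
are reproducible byte-for-byte.

## Known limitations

- The grid cannot express parameters off its nodes; recovery error is
  bounded below by grid resolution (0.05 / 0.1 per node spacing).
- LLE ties are resolved lexicographically; the reported point is then a
  convention, and `n_ties` should be consulted before interpreting it.
- The five-parameter perseveration variant of the model is not
  implemented (its functional form is not available); the four-parameter
  model was preferred upstream anyway.
- R0, α_G and fit quality are mutually correlated in this model family;
  single-session point estimates are noisy and group-level contrasts are
  the intended use.
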