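# Methods

## Task model

The task is a two-armed probabilistic reversal bandit with perfectly
anticorrelated outcome probabilities: the currently "correct" option
rewards (+1) with probability 0.8 and punishes (−1) otherwise; the other
option has the inverted probabilities. A default session has 160 trials:
a 55-trial stable pre-reversal phase, a 70-trial reversal phase, and a
35-trial stable post-reversal phase. The contingency switches four times.
The source description fixes the alternation pattern (after 15 or 20
trials) but not the placement of the first switch; we place it at the
first trial of the reversal phase, giving switches at trials 56, 71, 91
and 106 (1-based), with the final 20-trial segment's contingency
persisting through the post phase. All of this is configurable
(`TaskConfig`); schedules are pure functions of the configuration.
Trial indices are 1-based in all files and reports.

Outcomes are coded +1/−1. The anticorrelation of the two options is
sometimes written as `Q_uc = 1 − Q_c`, which presumes values on [0, 1];
with ±1 outcome coding the internally consistent counter-update is the
one we implement, `δ_uc = −R − Q_uc`, which drives `Q_uc` toward `−Q_c`.
Under full double updating from symmetric initial values the two values
are exactly antisymmetric on every trial, which the tests assert.

Initial values are (0, 0) (configurable). Missed responses are supported
in the data model (a validity flag; invalid trials contribute no
likelihood and trigger no update) but are not produced by the simulator
unless a missed-response rate is requested.

## Model space and likelihood

Six delta-rule models: {single update, double update, individually
weighted double update} × {one learning rate, separate reward/punishment
rates}, each with a softmax choice rule (inverse decision noise β). The
individually weighted variant scales the unchosen-option update by
κ ∈ [0, 1]; κ is implicitly 0 in SU and 1 in DU, so the single- and
full-double-update models are exact nested special cases — a property the
test suite checks as a likelihood identity. For two-rate models the
unchosen-option update uses the rate selected by the received outcome, so
the effective unchosen-option rates are κ·α_rew and κ·α_pun. With
outcomes in {−1, +1}, rates in [0, 1] and initial values in [−1, 1],
every update is a convex combination, so values remain in [−1, 1]
(property-tested).

## Estimation

Each session × model is fitted by maximum a posteriori estimation in
unconstrained space: logit transform for learning rates and κ, log for β.
Priors are independent Gaussians in that space with means at the
transform of the native means (0.5 for rates, 0.1 for κ, 1.0 for β) and
unit variance. Placing the Gaussians in transformed rather than native
space keeps the prior support consistent with the parameter bounds; it is
the convention of the estimation toolboxes standard in this literature.

Optimization is multistart L-BFGS-B (numerical gradients, objective
tolerance 1e−6): the first start at the prior mean, the rest jittered
with SD 2 in unconstrained space, 10 restarts by default. The heavy
recovery studies in the tests and the acceptance script use 2–5 restarts;
spot checks at 10 restarts reproduce the same optima, and the
grid-search oracle in the acceptance suite bounds the optimizer's
shortfall at zero to within 1e−3 on seeded sessions.

Log model evidence is the Laplace approximation at the MAP,
`lme = log p(y, θ̂) + (d/2)·log 2π − ½·log det H`, with H the
central-difference Hessian of the negative log-joint (step 1e−3). If H is
not positive definite the code falls back to a BIC-style penalty
`log p(y, θ̂) − (d/2)·log n` and flags the fit (`hessian_ok = False`).

Sessions are screened for chance-level responding: the fraction of
choices explained is the geometric-mean per-trial likelihood
`f = exp(−NLL/n)`; `round(f·n)` successes in `n` trials are tested
one-sided against 0.5 by an exact binomial test, and a subject is
excluded when no model beats chance in one of their sessions.

Known estimation behavior worth stating plainly: on single 160-trial
sessions MAP estimates are shrunk toward the prior means (κ markedly so,
toward 0.1) and maximum-likelihood estimates of β are heavy-tailed. Mean
recovered parameters are therefore *not* unbiased for the generating
values; what is preserved — and what the recovery tests assert — is the
true-vs-recovered κ correlation and the ordering of condition means.

## Model selection

Random-effects BMS: subject-level log evidences enter a variational
Dirichlet-multinomial scheme (responsibilities
`u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))`, pseudo-counts
`α_k = α₀ + Σ_n u_nk`, uniform prior α₀ = 1, convergence 1e−6 on α).
Exceedance probabilities are Monte-Carlo estimates over the Dirichlet
posterior (10⁶ seeded draws by default; the two-model case is
cross-checked against the closed-form Beta tail in the tests). The
Bayesian omnibus risk compares the variational free energy of the
alternative against the exact evidence of the null model in which all
frequencies equal 1/K; protected exceedance probabilities are
`PXP = (1 − BOR)·XP + BOR/K`. At perfectly symmetric evidence PP and PXP
equal 1/K exactly while BOR converges to ≈ 0.79 rather than 1 — the
n-dependent free-energy terms cancel and a constant gap remains; this is
a property of the standard free-energy construction, not an
implementation artifact.

Frequency-equality questions (are two groups', or two conditions', model
frequencies the same?) are answered by a free-energy contrast: the pooled
model (one frequency vector) against independent per-cohort models, with
`P(shared) = 1/(1 + exp(F_indep − F_pooled))` under equal prior odds. The
underlying publication names no algorithm for this step; this contrast is
this package's defined procedure and is reported as such. Pooling across
matched conditions sums each subject's log evidences before selection.

## Behavioral statistics

Win-stay/lose-stay: a trial pair (k, k+1) qualifies when both trials are
valid; "stay" means the same choice on both; the conditioning outcome and
the phase attribution come from the leading trial k (pairs spanning a
phase boundary count toward the leading phase). Correct-choice rates are
per-phase proportions of choosing the currently better option. The exact
two-sided binomial test uses the point-probability ("minlike")
convention — the only two-sided rule that reproduces all four published
blinding p-values. The 2×2 count tests are Pearson chi-square without
continuity correction. Paired effect sizes are Cohen's d on differences
and the matched rank-biserial correlation from the signed-rank
construction (zero differences dropped). Mixed-design ANOVAs are out of
scope; the pipeline exports tidy per-subject tables for off-the-shelf
statistics software instead.

## Synthetic cohorts

The generator emulates the study structure the analysis assumes: two
groups (30 and 31 subjects), each subject doing one sham and one verum
session in counterbalanced order (alternating by subject index), 160
trials per session. Subject-level parameters are drawn from truncated
Gaussians in native space; the defaults are the published group-level
means and SDs of the winning model (sham: α 0.44 ± 0.16, κ 0.33 ± 0.12,
β 5.98 ± 3.00; anodal verum: α 0.47 ± 0.19, κ 0.41 ± 0.15,
β 5.58 ± 2.33; the cathodal group's verum condition is generated like
sham, where no effect was reported). Parameters correlate across a
subject's two sessions through a latent Gaussian with correlation 0.7 —
the real test–retest correlation is unreported, so this value is an
explicit, configurable choice mimicking plausible stability.
`effect_injection` builds controlled variants in which the *only*
condition difference is a κ shift in the anodal verum condition (0.08
reproduces the published 0.33 → 0.41 means), for power and null studies.

What the generator does not emulate: reaction times, missed responses
(unless requested), learning across sessions, any relationship between
parameters and demographics, and session-order effects. Passing recovery
tests on these cohorts therefore shows the pipeline is correct and
well-powered *under the stated generative assumptions*, not that the
published empirical estimates are right — the raw study data are not
deposited, and the published group means serve here as generative
defaults, not as targets.

## Problem sizes and numerical choices

Recovery studies in the tests and acceptance script use the cohort sizes
above with 2 optimizer restarts per fit; the grid oracle uses 21³ points
over the ±4 unconstrained box on 40-trial sessions; exceedance sampling
uses 2×10⁵–10⁶ draws; the κ → lose-stay mechanism uses 2,000 simulated
agents per κ value; posterior-predictive simulation defaults to 10,000
simulations per session in the pipeline configuration (examples and tests
use reduced counts). Ties between equal option values are resolved by the
softmax draw itself (probability 0.5), never by option index. Degenerate
inputs are defined, not crashed on: zero-valid-trial sessions fit to the
prior means with a warning flag, stay statistics with no qualifying pairs
return NaN with a `defined = False` flag, and all-zero paired differences
yield NaN effect sizes.

## Known limitations

Single-session MAP estimates are shrinkage-biased (see Estimation), so
group-mean parameter recovery is attenuated; condition *orderings* are
recovered reliably: the κ-ordering recovery rate at the published effect
size is ≈ 0.90–0.95 across seed families (the ordering of the derived
α_uc = κ·α is recovered slightly more often), limited by the fact that
the anodal condition's lower β shrinks its κ estimates slightly more
than sham's.
Nested-model degeneracy is inherent: cohorts generated from SU can be won
by iDU with κ ≈ 0 (flagged, not treated as failure). Hierarchical
(empirical-Bayes) fitting, MCMC posteriors, family-level BMS and
fixed-effects model comparison are out of scope.
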