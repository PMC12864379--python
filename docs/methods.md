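# Methods

## Model

The response is a 4-level ordinal Frankl rating `Y` observed for each
child at the end of program phases I-III (three rows per child). The
proportional-odds cumulative logit model is

    logit P(Y <= j | x) = theta_j - x' beta,   j = 1, 2, 3,

with strictly ordered thresholds and a slope vector shared across the
three cumulative logits. The sign convention (`- x'beta`) makes positive
slopes mean *more cooperative* ratings; it is the convention under which
the fitted slopes (0.90 for `Phase`, 2.48 for `Init.Rating`) and the
predicted improvement probabilities are mutually consistent, and it
matches the `clm`-style parameterization used by mainstream ordinal
regression software. `Phase` enters numerically (1, 2, 3) with a single
slope; categorical covariates are dummy coded against their first level;
a model may contain at most one `Phase x X` product term, with `X`
required among the main effects — the unique reading under which the
candidate space over ten predictors has `2^10 + 9 * 2^8 = 3,328` members.

Baseline (first-visit) ratings do not enter as response rows; the
baseline conditions the model only through the binary `Init.Rating`
(0 = first visit `--`/`-`, 1 = `+`). Fitting the 255 phase-level rows
reconstructed from the built-in count fixture reproduces the published
coefficients to well under the 2-decimal printing precision, which
confirms this reading empirically; including baseline rows as "phase 0"
does not.

Repeated measures are pooled: the likelihood treats a child's three
phase rows as independent given covariates. Dependence is acknowledged
at the *resampling* level instead (see Bootstrap below).

## Estimation

Maximum likelihood with an analytic gradient and analytic observed
information. Threshold ordering is enforced by the log-increment
reparameterization `theta_1, theta_1 + exp(g_2), theta_1 + exp(g_2) +
exp(g_3)`. The default optimizer is a damped Newton iteration in
`(theta, beta)` space with step halving (gradient tolerance 1e-8,
max 500 iterations); when Newton fails (e.g. indefinite information far
from the optimum, empty response category), the fit falls back to BFGS
on the reparameterized scale. Data are internally collapsed to unique
(covariate-pattern, response) cells with frequency weights; the weighted
and row-expanded likelihoods are identical, and bootstrap refits become
cheap. `vcov` is the inverse of the analytic observed information at the
MLE (cross-checked against finite differences in the test suite).

Degenerate fits — an empty response category (the affected threshold
drifts), apparent complete separation (|beta| > 30), or a non-PSD
information matrix — are returned but flagged; the bootstrap machinery
excludes and counts them.

Confidence intervals: `conf_int(method="wald")` gives symmetric
normal-theory intervals; `method="profile"` inverts the signed
likelihood-ratio statistic per slope. The published intervals for the
final model are asymmetric and coincide with the profile intervals
(e.g. 1.72-3.36 for `Init.Rating`, where Wald gives 1.67-3.29), as
expected from `clm`-style software whose `confint` defaults to profile
likelihood.

The non-proportional alternative gives each cumulative logit its own
threshold and slope vector (`3 (1 + p)` parameters). Monotonicity of the
implied cumulative probabilities is not enforced — it is the standard
unconstrained alternative for the proportional-odds LRT — but parameter
configurations assigning non-positive probability to an observed cell
are rejected with an infinite objective, and fits with non-monotone
cumulative probabilities anywhere in the observed design are flagged.
On the fixture the LRT is 7.64 on 4 df (p = 0.11): no evidence against
proportional odds.

BIC is `-2 loglik + k log n` with `n` the number of long-format rows in
the fit, matching the referenced software's convention.

Pearson goodness of fit sums `(O - E)^2 / E` over observed covariate
patterns crossed with the four categories, with `df = patterns * 3 - k`.
Cells with expected counts below a configurable floor (default 1)
trigger a warning rather than automatic merging. On the fixture the
statistic is 19.46 over 6 patterns; with `df = 13` (our convention)
p = 0.109. The published p of 0.148 corresponds to the same statistic at
`df = 14`, so the underlying statistic — the part the data determine —
agrees exactly and only the df bookkeeping differs; we treat the printed
p as a consistency check, not a target.

## Count fixture

The per-phase category counts for both cohorts are reconstructed from
the published percentage tables by nearest-integer rounding of
`percent * n / 100`; every row is asserted to sum to its cohort size
(45 / 40), and all eight rows pass. Marginal counts determine the
modelling dataset exactly (each count unit becomes one pseudo-child
row), but not the *joint* baseline-by-phase tables for the uncooperative
cohort; the Stuart-Maxwell helper therefore refuses marginal input
whenever the baseline spreads over more than one category.

## Model selection

The one-standard-error rule: (1) draw B = 2,000 bootstrap copies of the
selection sample — children with complete information on all vocabulary
predictors, so every candidate is compared on the same data; (2) refit
every candidate on every copy and record BIC; (3) with `m*` the model of
minimum mean bootstrap BIC and `se` the standard deviation of its B
scores, return the candidate with fewest free parameters whose mean BIC
lies in `(mean* - se, mean* + se)` (ties: lower mean, then canonical
order).

Resampling choices the source analysis leaves open, exposed as flagged
options with these defaults: the resampling unit is the *child* (all
three phase rows move together, preserving within-child dependence), and
draws are stratified by baseline cohort (45 + 40 drawn within cohort) so
no replicate loses all `Init.Rating` variation. Replicates in which a
model is degenerate are excluded from that model's mean/SD and counted;
a model invalid in more than B/2 replicates is dropped from selection
with a warning.

A sobering empirical note, measured with this package's own machinery
at study scale (85 children): the bootstrap standard deviation of a
candidate's BIC is of order 20-25, while the BIC gap between
{Phase, Init.Rating} and the Init.Rating-only model is of order 10-25.
The 1se interval around the minimum therefore frequently contains the
Init-only model, and — being the more parsimonious candidate — it is
then selected. Recovery of the full sparse truth by the 1se rule at this
sample size is consequently closer to a minority event than a reliable
property; the minimum-mean-BIC model, by contrast, contains both `Phase`
and `Init.Rating` in nearly every replication. The selection-consistency
test records this honestly (see Known limitations).

## Improvement probabilities and bootstrap intervals

Improvement events: `P(Y >= 3)` for `Init.Rating = 0`, `P(Y = 4)` for
`Init.Rating = 1`, evaluated at each phase. Percentile-bootstrap 95%
intervals refit only the *selected* spec per replicate (selection is not
re-run; a selection-aware analysis can be assembled from the library
pieces but is not the default), all six intervals coming from one shared
set of replicates. Interval endpoints are empirical quantiles with
linear interpolation between order statistics, so a seed reproduces
bit-identically. The fixture intervals at B = 2,000 agree with the
published ones to about 0.01 — exact agreement is impossible without the
source's resampling unit and RNG, so the intervals are treated as
stochastic consistency checks.

## Stuart-Maxwell test

Statistic `d' V^- d` with `d` the first K-1 row-minus-column marginal
differences and `V` the usual null covariance (diagonal
`n_i+ + n_+i - 2 n_ii`, off-diagonal `-(n_ij + n_ji)`), computed with a
Moore-Penrose inverse. Default `df = rank(V)`, which handles the
singular tables of a single-category baseline; `df_method="categories"`
gives the fixed K-1 convention of much mainstream software. On the
cooperative-cohort fixture tables the statistics are 1 / 5 / 4 (phases
I-III); the rank convention gives p = 0.32 / 0.08 / 0.14 and the K-1
convention 0.80 / 0.17 / 0.26 — the latter matching the published
"all greater than 0.17", so that bound evidently used df = K-1. No
continuity correction.

## Synthetic-data generator

Emulates the study structure: cohort sizes 45/40; uncooperative baseline
split 6:39 over `--`/`-`; covariate marginals per cohort from the
published summary table; ages 7-12 weighted to match the reported
quartiles (8/9/10) and mean (~9.2); dmft as a negative binomial
(size 0.8, mean 4.3) right-truncated at 11, whose truncated
distribution has quartiles 0/2/5 and mean ~3.0; per-covariate MCAR
missingness at the published observed-count rates. Phase ratings are
drawn from the proportional-odds process at the configured
`(theta, beta)`; the default truth is the fixture MLE
(theta = (-1.60, 1.29, 7.24), `Phase` 0.90, `Init.Rating` 2.48).
Ratings are generated from true covariate values; missingness is applied
only to the recorded values afterwards.

What the generator does *not* emulate: within-child dependence beyond
covariates (phases are conditionally independent, as the analysis model
assumes; an optional child-level latent shift `child_effect_sd` exists
for stress-testing the child-level bootstrap), informative missingness,
and any treatment-pathway feedback (e.g. anesthesia referral). Passing
tests on this generator therefore validate the estimation and resampling
machinery under the analysis model's own assumptions, not robustness to
their violation.

Problem sizes used by the test suite were chosen to exercise each
property at the scale that makes it informative: study-sized cohorts
(85 children) for coverage and selection behavior, 2,000-10,000 children
for parameter recovery and law-of-large-numbers checks, B = 200-2,000
bootstrap replicates depending on the role of the interval.

## Known limitations

* The 1se selection-consistency check (majority of 20 study-sized seeds
  recovering {Phase, Init.Rating}) fails under the default generator for
  the structural reason quantified above: at n = 85 the bootstrap BIC
  noise is comparable to the Phase effect's BIC gap, so the 1se rule
  usually backs off to the Init-only model. The behavior is a property
  of the rule at this sample size, not of the implementation (the rule's
  definition is verified against hand-computed examples, and minimum-
  mean-BIC selection recovers the truth's subgroup consistently).
* Published bootstrap interval endpoints, the minimum-BIC model's
  coefficients (which depend on unpublished child-level covariates), and
  the uncooperative-cohort Stuart-Maxwell p-values (which need
  unpublished joint tables) cannot be reproduced exactly; they are
  covered by coverage, sign/magnitude, and bound checks instead.
* No other link functions, no random effects or GEE, no Bayesian
  estimation, no AIC or penalized search, and no multiplicity adjustment
  across the six intervals.
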