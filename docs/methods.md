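# Methods

`bqdesign` implements a Bayesian adaptive dose-ranging design for phase II
trials with J arms (arm 1 = placebo/control), a binary toxicity endpoint and a
binary, ordinal or continuous efficacy endpoint. This note records the model,
the decision rules, the numerical choices, and what the simulation machinery
does and does not emulate.

## Probability model

**Toxicity.** At dose j, toxicity is Bernoulli(pi_j) with a conjugate
Beta(a_T, b_T) prior, so after m_j events in n_j patients the posterior is
Beta(m_j + a_T, n_j − m_j + b_T). Defaults a_T = b_T = 1 (vague).

**Efficacy (quasi-Bernoulli).** The efficacy outcome y is standardized onto
[0, 1] via y* = (y − lower_j) / (upper_j − lower_j). For bounded endpoints the
bounds are the declared endpoint boundaries (0/1 for binary, 0/K−1 for a
K-level ordinal score); for continuous endpoints they are the per-dose
observed minimum and maximum. The standardized outcome is then modelled *as
if* Bernoulli, separately in the two toxicity strata (x = 0 and x = 1), which
gives Beta posteriors with possibly fractional pseudo-event sums
s_jk = sum of y* over patients at dose j with toxicity outcome k:
theta_jk ~ Beta(s_jk + a_E, n_jk − s_jk + b_E). This is a quasi-likelihood:
the posterior is a coherent (and consistent) summary of the conditional mean
even though y* is not actually binary, and it keeps everything closed-form
across endpoint types. Defaults a_E = b_E = 1, identical across doses and
strata (the data rarely support stratum-specific priors and none are implied
by the construction).

**Marginal efficacy.** Posterior draws of the mean efficacy on the original
scale mix the strata draw-by-draw:

    mu_j(t) = pi_j(t) * g_j^{-1}(theta_j1(t)) + (1 − pi_j(t)) * g_j^{-1}(theta_j0(t)),

with g_j^{-1}(theta) = theta (upper_j − lower_j) + lower_j. Draws of pi,
theta_0, theta_1 are sampled independently across doses and strata (the model
factorizes; dependence enters only via the isotonic transform below).

**Monotonization.** Monotone dose-toxicity is imposed on the posterior draws:
each draw vector (pi_1(t), …, pi_J(t)) is replaced by its weighted
non-decreasing least-squares fit (pool-adjacent-violators), with weights equal
to the reciprocal of the per-dose posterior variances, estimated empirically
from the unconstrained draw matrix and fixed across draws. The same transform
is applied to the mu draws when `isotonic_efficacy` is on (default), matching
the common assumption of monotone dose-efficacy; it can be switched off per
endpoint. The mixture in mu is computed from the *unconstrained* pi draws and
the transform is applied afterwards to the mu matrix itself; this keeps the
two monotonizations independent and is the reading most consistent with
applying PAVA "to the mu draws".

## Decision rules

All posterior probabilities are draw proportions with strict inequalities
(no continuity correction); ties in argmin/argmax break to the lower dose
index (conservative and deterministic).

* **Admissibility.** Dose j in 2..J stays in the admissible set A iff
  Pr(pi_j > pi_1 + pi_bar) < C_T (safety) and Pr(mu_j <= mu_1) < C_E
  (futility). A is recomputed from all accumulated data at every interim, so
  a dose dropped at one interim can re-enter later. Defaults pi_bar = 0.3,
  C_T = 0.9, C_E = 0.7.
* **Proof-of-concept.** At the final analysis PoC is established iff
  max_j Pr(mu_j > mu_1) > C_PoC, with C_PoC calibrated by simulation (below).
* **MED.** Among A, the dose whose posterior-mean efficacy is closest to
  mu_1_hat + Delta (Delta = 0.4 by default for the continuous benchmark
  setting). No constraint that the MED beat placebo is added beyond
  admissibility; the rule is implemented exactly as the distance argmin.
* **MUD.** Among A, the dose with the largest posterior-mean utility, with
  U = mu − w1·pi − w2·pi·1(pi > rho) (w2 = 0 recovers the simple linear
  tradeoff U = mu − w·pi; default w = 2). The utility estimate is the
  posterior mean of the per-draw utility, which for the linear form equals
  mu_hat − w·pi_hat. An optional flag restricts the MUD to doses at or above
  the selected MED (off by default).
* **Adaptive randomization.** p1_j and p2_j are the proportions of posterior
  draws in which dose j is the per-draw MED / MUD (the MED and MUD rules
  applied draw-wise, restricted to the current A). Admissible doses score
  tau·p1_j^nu + (1 − tau)·p2_j^nu (tau = 0.5, nu = 1 by default; nu = 0 gives
  equal randomization). The most-likely MED and most-likely MUD are each
  boosted to p_max, the largest entry among the target-dose probabilities
  (restricted to p1 when tau = 1, to p2 when tau = 0), the control receives
  min(p_max, 1/(J−1)), inadmissible doses receive 0, and the scores are
  normalized. The boost is applied before normalization and only to those
  argmax doses.

## Trial conduct

Stage 1 randomizes c_1 patients equally (balanced counts; remainder arms
chosen uniformly at random, so "equal randomization" is honored as near-exact
balance rather than multinomial noise). At each later stage the posteriors,
A and the randomization vector are refreshed from all accumulated data and
frozen for the stage; the stage's c_k patients are then assigned by
independent multinomial sampling. If A is empty at an interim the trial stops
(no MED/MUD). Outcomes are assumed immediately observable. Default staging
for the continuous benchmark: (100, 25, 25, 25, 25); ordinal
(120, 30, 30, 30, 30); binary (80, 20, 20, 20, 20).

Each trial consumes two independent random streams spawned from one seed —
one for design decisions (posterior draws, randomization), one for simulated
patient outcomes — so design Monte-Carlo noise is isolated from outcome noise
and runs are exactly reproducible.

## Calibration of C_PoC

The rejection rule is monotone in the cutoff, so a single simulation pass
suffices: simulate the design on a flat null scenario, record each trial's
final statistic max_j Pr(mu_j > mu_1) (early-stopped trials contribute 0 —
they can never reject), and take the empirical (1 − alpha) quantile (linear
interpolation). Re-simulating the null with fresh seeds then yields a
rejection rate within binomial Monte-Carlo error of alpha. A grid search over
cutoffs would give the same answer at many times the cost.

## Synthetic outcomes

Outcomes are generated from a latent bivariate normal: (x~, y~) with means
(0, mu_j), variances (1, sigma²) and correlation rho; toxicity is
x~ > Phi^{-1}(1 − pi_j) (so the marginal toxicity rate is exactly pi_j),
continuous efficacy is y~, ordinal efficacy bins y~ at shared increasing
cutoffs, binary efficacy thresholds the standardized latent at
Phi^{-1}(1 − piE_j). Defaults rho = 0.3, sigma = 1. The built-in library
holds ten continuous, six ordinal and six binary dose-response shapes plus
flat null curves, each labelled with its true MED/MUD; the ordinal and binary
shapes reuse six of the continuous latent curves. The ordinal scenarios'
printed target means imply a specific cutoff vector that is not part of the
library; `fit_ordinal_cutoffs` least-squares-fits a shared cutoff vector to
the target means (with a minimum category width, since the unconstrained
optimum can collapse categories) and is documented as approximate — a single
shared vector cannot match every dose exactly. The utility weights implied by
the ordinal and binary utility tables (4 and 1 respectively, vs 2 for the
continuous table) are stored as per-scenario metadata; likewise the implied
target differences Delta (0.75 ordinal, 0.2 binary, inferred from the
labelled MEDs).

This generator emulates correlated toxicity/efficacy outcomes with exact
marginals; it does not emulate delayed or missing outcomes, patient
heterogeneity beyond the latent correlation, non-normal continuous efficacy,
or time trends in enrollment. Passing tests therefore demonstrate the
engine's decision-theoretic behavior under the stated generative model, not
robustness to real-data pathologies outside it.

## Numerical choices and degenerate inputs

* T = 4,000 posterior draws by default: the Monte-Carlo standard error of a
  tail probability near 0.9 is ~0.005, small relative to every cutoff used.
* Continuous-endpoint standardization bounds are recomputed at each analysis
  from all accumulated data (one map per dose per analysis). A dose with
  fewer than two distinct efficacy values falls back to the pooled observed
  min/max; if the pooled range is also degenerate (all observed values
  identical) the theta draws are set to 1/2 and mu collapses to the single
  observed value.
* A dose whose draw column is numerically constant would give an infinite
  PAVA weight; it receives the largest finite weight among the other doses.
* Empty strata or arms simply return the prior (conjugacy with zero counts).
* Simulation sizes: operating characteristics and calibration use 2,000
  trials per scenario in the examples and test suite (4,000 in the
  reproduction script), with tolerances reported as three binomial standard
  errors; larger runs (e.g. 10,000) are a parameter away.

## Known limitations

* Time-to-event efficacy endpoints are out of scope (the quasi-Bernoulli
  device needs a bounded outcome).
* The outcome-score generalization of the utility (scores a_xy over joint
  outcome combinations) is an extension point, not implemented; the two
  implemented forms cover the linear and threshold-penalty tradeoffs.
* Randomization probabilities are frozen within a stage; no within-stage
  response adaptation.
* The isotonic transform assumes monotone dose-toxicity (always) and
  monotone dose-efficacy (by default); for non-monotone efficacy turn
  `isotonic_efficacy` off.
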