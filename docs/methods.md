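# Methods

This note documents the statistical content of `ipdmeta`: the models, the
estimation and inference machinery, the synthetic-data generator, and the
numerical decisions that a maintainer or careful user should know about.

## Models

Participant *j* of trial *i* (i = 1..K) has continuous final outcome
`Y_ij`, treatment indicator `treat_ij` in {0, 1}, and optionally a baseline
measurement `B_ij`.  The marginal model for the outcome vector of trial *i*
is Gaussian with mean `X_i beta` and covariance

    V_i = sigma2 * I + tau2 * t_i t_i' + tau_beta2 * 1 1'

where `t_i` is the trial's treatment column.  The fixed-effect design
contains either K trial intercepts (stratified) or one shared intercept
(random intercept, with the `tau_beta2` term active), optional baseline
coefficients (one per trial or shared; the baseline column is centred at
the trial's own baseline mean so intercepts remain interpretable as control
-group means), and always the treatment effect `theta` as the last column.
A common-treatment-effect variant drops the `tau2` term.  A single residual
variance is shared by all trials; trial-specific residual variances,
correlated random effects and non-Gaussian outcomes are out of scope.

## Estimation

The fixed effects are profiled out at their GLS value
`(X'V^-1 X)^-1 X'V^-1 y`, and the profiled log-likelihood (ML) or
restricted log-likelihood (REML = ML criterion − ½ log|X'V^-1X|) is
maximized over the variance components `psi = (sigma2[, tau2][, tau_beta2])`.

- **Low-rank algebra.**  Every column of `X_i` and every random-effect
  direction lies in the span of at most three per-trial vectors (ones,
  treatment, centred baseline).  Woodbury and determinant-lemma identities
  therefore reduce likelihood values, gradients, expected information and
  the Kenward-Roger adjustment to dense algebra on r×r Gram matrices
  (r ≤ 3).  Cost per likelihood evaluation is O(K); the data are touched
  once, when the design bundle is built.  The test suite pins the block
  evaluation to a dense n×n oracle at 1e-8.
- **Optimizer.**  Bounded L-BFGS-B on the variance scale (scaled by the
  starting residual variance) with the analytic gradient of the profiled
  criterion; lower bound 0 for the between-trial variances.  The boundary
  must be genuinely attainable — with few trials the ML profile is very
  often maximized at `tau2 = 0`, and the simulation records exactly that —
  which is why a log-variance parameterization is not used.  A Nelder-Mead
  fallback runs if the quasi-Newton pass fails.
- **Starting values.**  Method of moments: pooled within-trial two-group
  residual variance for `sigma2`; variance of per-trial mean differences
  minus the mean of their sampling variances (floored at 0) for `tau2`;
  variance of per-trial control means for `tau_beta2`.  These frequently
  land within one step of the optimum.
- **Convergence.**  Relative criterion change below 1e-13 or projected
  gradient below 1e-7, within 100 optimizer iterations (the cap mirrors
  the convergence indicator recorded by the simulation study).  A line
  search halted by floating-point rounding still counts as converged when
  the projected gradient at the returned point is below 1e-4 in scaled
  units; without this, optimizer bookkeeping — not statistics — would be
  reported as non-convergence.  Non-convergence is an outcome, not an
  exception: the engine records it and downstream metrics exclude those
  replicates.
- **Boundary and degenerate data.**  Variance estimates at or below 1e-10
  are snapped to exactly 0, so "median estimate exactly on the boundary"
  is representable.  Data fitted exactly by the fixed effects short-circuit
  to the boundary solution (unbounded likelihood, reported as +inf); data
  whose variation lies entirely between arms (none within) get a
  data-scaled floor on `sigma2` (1e-6 × starting value) to keep the
  near-singular covariance out of the catastrophic-cancellation regime.

## Confidence intervals for theta

Let `Phi = (X'V^-1X)^-1` at the estimates and `Phi_t` its treatment-effect
diagonal entry.

- **Standard**: `theta_hat ± z_{1-a/2} sqrt(Phi_t)`.
- **Satterthwaite**: t interval with
  `df = 2 Phi_t^2 / (g' W g)`, where `g_k = [Phi S_k Phi]_tt`,
  `S_k = X'V^-1 (dV/dpsi_k) V^-1 X`, and `W` is the inverse expected
  (REML-projected when fitting by REML) information of the variance
  components.
- **Kenward-Roger**: first-order adjusted covariance
  `Phi_A = Phi + 2 Phi [ sum_kl W_kl (Q_kl − S_k Phi S_l) ] Phi` with
  `Q_kl = X'V^-1 V_k V^-1 V_l V^-1 X` (the second-derivative terms vanish
  because V is linear in psi), used with the same degrees of freedom: for a
  single-parameter Wald statistic the KR moment rule reduces algebraically
  to the Satterthwaite expression, so the two intervals differ only through
  the variance.  If the adjustment lands below the unadjusted variance the
  interval is flagged, not rejected.

Design choices: *expected* rather than observed information for `W`
(standard KR practice; this is also why our degrees of freedom differ from
lmerTest's observed-information values in the third decimal); corrections
offered for REML fits only — ML fits get the standard interval, matching
how the estimation/CI combinations are used in practice; variance
components estimated exactly at 0 are retained in `W` through their
one-sided curvature, and dropped (with a warning) only if the information
matrix is singular; degrees of freedom are never rounded; quantiles come
from scipy to double precision.

## Synthetic data

The generator emulates an IPD meta-analysis of K randomized trials with
1:1 allocation and no baseline imbalance (final-score analyses only).
Defaults are the study conditions: theta = −9.66, tau2 = 7.79,
beta = 159.73, tau_beta2 = 233.99, sigma2 = 333.74 — values on a systolic
blood-pressure scale.  Three mechanisms: normal trial intercepts with a
random treatment effect; 220·Beta(15, 3) (negatively skewed) intercepts
with a random effect; and normal intercepts with a common effect.  The
scenario grid (`resources/scenarios.yaml`) varies K (5/10/20), trial sizes
(fixed 100; integer-uniform 30–1000; small/large mixtures; small-only
30–100), and halves/doubles `tau_beta2` (117/468) or `tau2` (3.9/15.6):
14 geometries × 3 mechanisms − 4 inapplicable cells = 38 scenarios.

Interpretation choices where the study description is ambiguous:
allocation is exactly balanced within trial (floor(n/2) treated, the odd
participant to control) rather than Bernoulli(½); trial sizes are drawn as
integers, endpoints inclusive.  What the generator does *not* emulate:
baseline imbalance, unequal allocation, trial-specific residual variances,
correlated random effects, missing data.  Passing tests therefore speak to
estimator behaviour under a correctly specified (or beta-misspecified-
intercept) Gaussian world, not to robustness against those features of
real IPD.

Randomness: each replicate draws its generator from
`SeedSequence(master_seed, hash(scenario:variant), rep_index)`, so any
replicate is reproducible in isolation and results are invariant to how
replicates are scheduled across workers.

## Replication engine and performance measures

One replicate = one generated dataset, four fits (stratified/random ×
ML/REML, with common-effect specifications under the common-effect
mechanism), and up to eight interval records (standard from ML; standard,
KR, Satterthwaite from REML).  Records stream to CSV and an interrupted
run resumes after the last completed replicate.

Per cell, over R converged replicates: mean % bias of theta_hat
(100·(mean−theta)/theta, signed relative to the negative true effect);
median % bias of tau2_hat (absent when true tau2 = 0); empirical SE
(divisor R−1); MSE (divisor R, so `mse = bias² + empSE²·(R−1)/R` holds
exactly); coverage per CI method with its binomial Monte-Carlo SE
`100·sqrt(c(1−c)/R)`; convergence % over all replicates.  1000 replicates
per scenario is the default (0.7 % Monte-Carlo error on 95 % coverage);
run times are recorded but are hardware-dependent diagnostics, not
comparable quantities.

## Known limitations

- Coverage and median-bias values are Monte-Carlo estimates; at 1000
  replicates, coverage moves by ±1–2 percentage points between seeds and
  medians of skewed variance estimates by several points.
- The reference implementation this package is compared against in its
  test suite (lme4/statsmodels) agrees to ~1e-4 or better on estimates,
  but no attempt is made to replicate any particular software's
  non-convergence behaviour; all metrics here condition on *this*
  package's convergence flags.
- The i-WIP-style real-data workflow (baseline-adjusted ANCOVA on actual
  trial data) is supported by the library surface (`load_ipd`,
  `baseline_adjustment`), but no real dataset ships with the package.
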