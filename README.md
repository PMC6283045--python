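# ipdmeta

One-stage individual participant data (IPD) meta-analysis of continuous
outcomes, together with the Monte-Carlo machinery to study how its
estimators behave.

## Who this is for

When raw participant-level data are available from K randomized trials of
the same treatment (say, blood-pressure lowering), a one-stage IPD
meta-analysis fits a single linear mixed model to all participants at once.
Within-trial clustering must be accounted for, and there are two competing
ways to do it — a separate fixed ("stratified") intercept per trial, or a
random intercept — combined with choices of estimation (ML or REML) and of
confidence-interval construction (standard normal, Kenward-Roger,
Satterthwaite).  This package implements all of those model/estimation/CI
combinations for continuous outcomes, and a replication engine plus a
38-scenario synthetic-data grid to measure their bias, empirical SE, MSE,
coverage and convergence.

## The models

For participant *j* in trial *i* with final outcome *Y_ij* and treatment
indicator *treat_ij* ∈ {0, 1}:

- **Stratified intercept**
  `Y_ij = beta_i + (theta + u_i) treat_ij + e_ij`,
  with `u_i ~ N(0, tau^2)` and `e_ij ~ N(0, sigma^2)`: one fixed intercept
  per trial, treatment effects drawn around the summary effect theta with
  between-trial variance tau^2.
- **Random intercept**
  `Y_ij = beta + u1_i + (theta + u2_i) treat_ij + e_ij`,
  with `u1_i ~ N(0, tau_beta^2)` independent of `u2_i ~ N(0, tau^2)`.

Either model can instead assume a **common effect** (tau^2 = 0), and either
can adjust for a baseline outcome measurement (ANCOVA form, baseline
centred at each trial's own mean).  Estimation maximizes the profiled
marginal likelihood (ML) or restricted likelihood (REML) over the variance
components, with the zero boundary attainable.  Confidence intervals for
theta are

- standard: `theta_hat ± z_{1-a/2} sqrt(Var(theta_hat))`,
- Satterthwaite: a t interval with moment-matching degrees of freedom,
- Kenward-Roger: the same degrees of freedom with a bias-adjusted
  (inflated) variance (REML only, as is standard practice).

All per-trial algebra goes through rank-≤2 Woodbury identities, so one
likelihood evaluation costs O(K) after a single O(n) pass over the data.

## Worked example

Simulate one base-case meta-analysis (10 trials × 100 participants,
theta = −9.66, tau² = 7.79, sigma² = 333.74) and fit the stratified model
by REML:

```python
from ipdmeta import load_scenario, generate_dataset, replicate_rng, save_ipd

cfg = load_scenario("Base")
data, _ = generate_dataset(cfg, replicate_rng(5, "Base", "normal_random", 0))
save_ipd(data, "example_ipd.csv")
```

```text
$ ipdmeta fit example_ipd.csv --model stratified --estimation REML --ci all
one-stage IPD meta-analysis: 10 trials, 1000 participants
model: stratified intercept, random treatment effect, REML
converged: True (iterations: 0)
theta_hat = -8.4469  (model-based SE 1.6186)
tau2_hat = 12.8143
sigma2_hat = 334.5842
     standard 95% CI: (-11.6192, -5.2745)  df=inf
           kr 95% CI: (-12.1083, -4.7854)  df=9.00
satterthwaite 95% CI: (-12.1083, -4.7854)  df=9.00
```

Reading the output: the summary treatment effect estimate is −8.45 mmHg
(true value −9.66 for this draw), the between-trial heterogeneity estimate
is 12.8, and the small-sample corrections replace the normal quantile by a
t quantile with 9.0 degrees of freedom — the corrected intervals are wider
than the standard one, reflecting the uncertainty in the variance
estimates that the standard interval ignores.  (Zero iterations means the
method-of-moments starting values already satisfied the convergence
criterion.)

The simulation study runs per scenario:

```bash
ipdmeta simulate --scenario B2 --dgm normal_random --reps 1000 --seed 20180813
ipdmeta summarize results/replicates_B2_normal_random.csv --out-dir results/summary
```

which writes one record per model/estimation/CI-method per replicate and
wide-format bias/coverage/convergence tables.

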