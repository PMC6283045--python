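# Simulation scenario geometries for the one-stage IPD meta-analysis study.
#
# Each block is one scenario: number of trials K, per-trial size rules (in
# trial order; "fixed" rules give a constant size, "uniform" rules draw an
# integer uniformly and inclusively from [low, high]), and the true
# parameter values.  Every geometry is crossed with three data-generating
# variants by expand_scenario_grid():
#   normal_random  - random treatment effect, normal trial intercepts
#   beta_random    - random treatment effect, 220*Beta(15,3) intercepts
#                    (C1/C2 excluded: no tau_beta2 to vary)
#   normal_common  - common treatment effect (tau2 forced to 0; D1/D2
#                    excluded: cannot halve or double a zero variance)
scenarios:
- id: Base
  K: 10
  sizes: [{count: 10, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: A1
  K: 5
  sizes: [{count: 5, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: A2
  K: 20
  sizes: [{count: 20, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B1
  K: 10
  sizes: [{count: 10, kind: uniform, low: 30, high: 1000}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B2
  K: 10
  sizes:
  - {count: 5, kind: uniform, low: 30, high: 100}
  - {count: 5, kind: uniform, low: 900, high: 1000}
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B1-A1
  K: 5
  sizes: [{count: 5, kind: uniform, low: 30, high: 1000}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B1-A2
  K: 20
  sizes: [{count: 20, kind: uniform, low: 30, high: 1000}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B2-A1
  K: 5
  sizes:
  - {count: 2, kind: uniform, low: 30, high: 100}
  - {count: 3, kind: uniform, low: 900, high: 1000}
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B2-A2
  K: 20
  sizes:
  - {count: 10, kind: uniform, low: 30, high: 100}
  - {count: 10, kind: uniform, low: 900, high: 1000}
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: B3
  K: 10
  sizes: [{count: 10, kind: uniform, low: 30, high: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: C1
  K: 10
  sizes: [{count: 10, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 117.0
  sigma2: 333.74
- id: C2
  K: 10
  sizes: [{count: 10, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 7.79
  beta_mean: 159.73
  tau_beta2: 468.0
  sigma2: 333.74
- id: D1
  K: 10
  sizes: [{count: 10, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 3.9
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
- id: D2
  K: 10
  sizes: [{count: 10, kind: fixed, n: 100}]
  theta: -9.66
  tau2: 15.6
  beta_mean: 159.73
  tau_beta2: 233.99
  sigma2: 333.74
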