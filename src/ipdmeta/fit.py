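"""ML and REML estimation of the one-stage IPD meta-analysis models.

The variance components are maximized directly on the variance scale with a
bounded quasi-Newton method (L-BFGS-B, central-difference gradients), with a
Nelder-Mead fallback if the line search fails.  The lower bound 0 for the
between-trial variances is genuinely attainable: with few trials the REML/ML
profile is often maximized at tau2 = 0, and the simulation study records
exactly that boundary behaviour, so a log-variance parameterization would be
wrong here.  Estimates below 1e-10 are snapped to exactly 0.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import DesignBundle, IPDDataset, ModelSpec, build_design
from .exceptions import FittingError, ValidationError
from .likelihood import block_state, marginal_loglik

__all__ = ["FitResult", "fit", "fit_all_combinations", "starting_values"]

SNAP_TOL = 1e-10          # variance estimates at or below this become exactly 0
SIGMA2_FLOOR = 1e-12      # optimizer lower bound keeping V invertible


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``theta_hat`` is the summary treatment effect (last fixed-effect
    coordinate) and ``var_theta`` its model-based GLS variance.  ``tau2_hat``
    is present only for random treatment effects, ``tau_beta2_hat`` only for
    random intercepts.  ``loglik`` is the ML or REML criterion value at the
    optimum.  A fit that did not converge keeps its (untrusted) estimates but
    must be excluded from downstream performance metrics.
    """

    theta_hat: float
    var_theta: float
    fixed_effects: np.ndarray
    fixed_names: list
    fixed_cov: np.ndarray
    sigma2_hat: float
    tau2_hat: float | None
    tau_beta2_hat: float | None
    loglik: float
    converged: bool
    n_iter: int
    runtime_seconds: float
    spec: ModelSpec
    varcomp: np.ndarray = field(repr=False)
    varcomp_names: list = field(repr=False)
    design: DesignBundle = field(repr=False, default=None)


def starting_values(design: DesignBundle) -> np.ndarray:
    """Method-of-moments starts in bundle varcomp order.

    sigma2: pooled within-trial two-group residual variance; tau2: variance
    of the per-trial mean differences minus the mean of their sampling
    variances (floored at 0); tau_beta2: variance of the per-trial control
    means.  These put the optimizer within a few steps of the optimum for
    well-behaved data.
    """
    n, m = design.n, design.n_treat
    nc = n - m
    dof = np.maximum(design.n_total - 2 * design.K, 1)
    sigma2_0 = float(design.ss_within.sum() / dof)

    start = [max(sigma2_0, SIGMA2_FLOOR)]
    diffs = design.mean_treat - design.mean_ctrl
    s2_trial = design.ss_within / np.maximum(n - 2, 1)
    samp_var = s2_trial * (1.0 / m + 1.0 / nc)
    for name in design.varcomp_names[1:]:
        if name == "tau2":
            v = float(np.var(diffs, ddof=1) - samp_var.mean()) if design.K > 1 else 0.0
            start.append(max(v, 0.0))
        else:  # tau_beta2
            v = float(np.var(design.mean_ctrl, ddof=1)) if design.K > 1 else 0.0
            start.append(max(v, 0.0))
    return np.asarray(start)


def fit(data: IPDDataset, spec: ModelSpec, design: DesignBundle | None = None) -> FitResult:
    """Fit one model specification by maximizing the (RE)ML criterion.

    Non-negativity of the variance components is enforced through bounds;
    convergence requires the optimizer to meet its tolerance within
    ``spec.max_iter`` iterations.  Optimizer failure is reported through
    ``converged=False``, not an exception — in the simulation study
    non-convergence is an outcome, not an error.
    """
    t0 = time.perf_counter()
    if design is None:
        design = build_design(data, spec)
    if spec.treatment_mode == "random" and design.K < 2:
        raise ValidationError(
            "a random treatment effect requires at least 2 trials"
        )

    x0 = starting_values(design)
    if x0[0] <= 1e-8:
        # essentially no within-trial, within-arm variation: check whether the
        # fixed effects alone reproduce the data, in which case the likelihood
        # is unbounded and every variance sits on its zero boundary
        st0 = block_state(np.r_[1.0, np.zeros(design.q - 1)], design, "ML")
        rss = st0.ytviy - float(st0.beta @ st0.xtvix @ st0.beta)
        dof = max(design.n_total - design.p, 1)
        if rss / dof <= SNAP_TOL:
            psi = np.zeros(design.q)
            names = design.varcomp_names
            return FitResult(
                theta_hat=float(st0.beta[design.theta_index]),
                var_theta=0.0,
                fixed_effects=st0.beta,
                fixed_names=design.fixed_names,
                fixed_cov=np.zeros((design.p, design.p)),
                sigma2_hat=0.0,
                tau2_hat=0.0 if "tau2" in names else None,
                tau_beta2_hat=0.0 if "tau_beta2" in names else None,
                loglik=float("inf"),
                converged=True,
                n_iter=0,
                runtime_seconds=time.perf_counter() - t0,
                spec=spec,
                varcomp=psi,
                varcomp_names=list(names),
                design=design,
            )
        # variation exists but sits between, not within, arms; keep sigma2
        # away from the cancellation regime near its zero boundary
        x0[0] = rss / dof
        sigma2_floor = max(SIGMA2_FLOOR, 1e-6 * x0[0])
    else:
        sigma2_floor = SIGMA2_FLOOR
    scale = max(x0[0], 1.0)
    lb = np.zeros(design.q)
    lb[0] = sigma2_floor / scale

    def objective(x):
        psi = np.maximum(x, lb) * scale
        try:
            st = block_state(psi, design, spec.estimation, need_cov=False,
                             need_grad=True)
        except FittingError:
            return 1e12, np.zeros_like(x)
        if not np.isfinite(st.criterion):
            return 1e12, np.zeros_like(x)
        return -st.criterion, -st.grad * scale

    def objective_fun(x):
        return objective(x)[0]

    x_start = np.maximum(x0 / scale, lb)
    res = optimize.minimize(
        objective,
        x_start,
        method="L-BFGS-B",
        jac=True,
        bounds=[(float(l), None) for l in lb],
        options={
            "maxiter": spec.max_iter,
            "ftol": 1e-13,
            "gtol": 1e-7,
        },
    )
    converged = bool(res.success) and res.nit <= spec.max_iter
    n_iter = int(res.nit)
    if not converged and res.nit <= spec.max_iter:
        # a line search halted by rounding still counts as converged if the
        # projected gradient vanishes at the returned point
        _, g = objective(res.x)
        pg = np.asarray(g, dtype=float).copy()
        at_bound = res.x <= lb + 1e-300
        pg[at_bound & (pg > 0)] = 0.0
        if np.isfinite(pg).all() and np.abs(pg).max() < 1e-4:
            converged = True
    if not converged:
        # derivative-free fallback from the same start
        res_nm = optimize.minimize(
            objective_fun,
            x_start,
            method="Nelder-Mead",
            bounds=[(float(l), None) for l in lb],
            options={"maxiter": 20 * spec.max_iter, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res_nm.success and res_nm.fun <= res.fun + 1e-6 * max(1.0, abs(res.fun)):
            res = res_nm
            converged = True
            n_iter = spec.max_iter  # cap: the fallback exceeded the primary budget

    psi = np.maximum(res.x, lb) * scale
    psi[psi <= SNAP_TOL] = 0.0
    psi_eval = psi.copy()
    if psi_eval[0] <= 0.0:
        psi_eval[0] = SIGMA2_FLOOR
    try:
        st = block_state(psi_eval, design, spec.estimation)
    except FittingError:
        converged = False
        st = None

    if st is None:
        p = design.p
        beta = np.full(p, np.nan)
        cov = np.full((p, p), np.nan)
        loglik = float("nan")
    else:
        beta, cov, loglik = st.beta, st.fixed_cov, st.criterion

    names = design.varcomp_names
    tau2 = float(psi[names.index("tau2")]) if "tau2" in names else None
    tau_beta2 = float(psi[names.index("tau_beta2")]) if "tau_beta2" in names else None

    return FitResult(
        theta_hat=float(beta[design.theta_index]),
        var_theta=float(cov[design.theta_index, design.theta_index]),
        fixed_effects=beta,
        fixed_names=design.fixed_names,
        fixed_cov=cov,
        sigma2_hat=float(psi[0]),
        tau2_hat=tau2,
        tau_beta2_hat=tau_beta2,
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        runtime_seconds=time.perf_counter() - t0,
        spec=spec,
        varcomp=psi,
        varcomp_names=list(names),
        design=design,
    )


def fit_all_combinations(data: IPDDataset, treatment_mode: str = "random") -> list:
    """Fit the four intercept/estimation combinations in a fixed order:
    stratified-ML, stratified-REML, random-ML, random-REML."""
    results = []
    for intercept_mode in ("stratified", "random"):
        for estimation in ("ML", "REML"):
            spec = ModelSpec(
                intercept_mode=intercept_mode,
                treatment_mode=treatment_mode,
                estimation=estimation,
            )
            results.append(fit(data, spec))
    return results
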