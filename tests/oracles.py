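"""Independent dense-matrix and closed-form oracles used by the tests.

Everything here deliberately avoids the package's block/Woodbury code
paths: designs are materialized as dense matrices, covariances as full
n x n arrays, and classical results (pooled two-sample t interval,
weighted mean-difference GLS) are written from their textbook forms.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def dense_design(data, spec):
    """Full fixed-effect design matrix in the package's column order
    (intercepts, baseline terms, treatment last)."""
    K, N = data.K, data.n_total
    ti = data.trial_index
    t = data.treat.astype(float)
    cols = []
    if spec.intercept_mode == "stratified":
        cols += [(ti == i).astype(float) for i in range(K)]
    else:
        cols.append(np.ones(N))
    if spec.baseline_adjustment != "none":
        b = data.y_baseline.astype(float).copy()
        for i in range(K):
            mask = ti == i
            b_i = b[mask] - b[mask].mean()
            if spec.baseline_adjustment == "stratified":
                col = np.zeros(N)
                col[mask] = b_i
                cols.append(col)
            else:
                b[mask] = b_i
        if spec.baseline_adjustment == "common":
            cols.append(b)
    cols.append(t)
    return np.column_stack(cols)


def dense_covariance(varcomp, data, spec):
    """Full marginal covariance V for variance components in canonical
    order (sigma2[, tau2][, tau_beta2])."""
    N = data.n_total
    ti = data.trial_index
    t = data.treat.astype(float)
    names = ["sigma2"]
    if spec.treatment_mode == "random":
        names.append("tau2")
    if spec.intercept_mode == "random":
        names.append("tau_beta2")
    vc = dict(zip(names, varcomp))
    V = vc["sigma2"] * np.eye(N)
    for i in range(data.K):
        mask = (ti == i).astype(float)
        if "tau_beta2" in vc:
            V += vc["tau_beta2"] * np.outer(mask, mask)
        if "tau2" in vc:
            tv = mask * t
            V += vc["tau2"] * np.outer(tv, tv)
    return V


def dense_loglik(varcomp, data, spec):
    """Gaussian marginal (restricted) log-likelihood at the GLS fixed
    effects, evaluated with full matrices."""
    X = dense_design(data, spec)
    V = dense_covariance(varcomp, data, spec)
    y = data.y_final
    Vi = np.linalg.inv(V)
    M = X.T @ Vi @ X
    beta = np.linalg.solve(M, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    ll = -0.5 * (len(y) * np.log(2 * np.pi) + logdetV + r @ Vi @ r)
    if spec.estimation == "REML":
        ll -= 0.5 * np.linalg.slogdet(M)[1]
    return ll, beta


def dense_covariance_derivatives(data, spec):
    """dV/dpsi_k as full matrices, canonical component order."""
    N = data.n_total
    ti = data.trial_index
    t = data.treat.astype(float)
    derivs = [np.eye(N)]
    if spec.treatment_mode == "random":
        D = np.zeros((N, N))
        for i in range(data.K):
            tv = (ti == i).astype(float) * t
            D += np.outer(tv, tv)
        derivs.append(D)
    if spec.intercept_mode == "random":
        D = np.zeros((N, N))
        for i in range(data.K):
            mask = (ti == i).astype(float)
            D += np.outer(mask, mask)
        derivs.append(D)
    return derivs


def dense_expected_information(varcomp, data, spec):
    """Expected (RE)ML information of the variance components via full
    matrices: I_kl = tr(P V_k P V_l)/2, with P the REML projection for
    REML and V^{-1} for ML."""
    X = dense_design(data, spec)
    V = dense_covariance(varcomp, data, spec)
    Vi = np.linalg.inv(V)
    if spec.estimation == "REML":
        M = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(M, X.T @ Vi)
    else:
        P = Vi
    derivs = dense_covariance_derivatives(data, spec)
    q = len(derivs)
    info = np.empty((q, q))
    for k in range(q):
        for l in range(q):
            info[k, l] = 0.5 * np.trace(P @ derivs[k] @ P @ derivs[l])
    return info


def pooled_t_interval(y_treat, y_ctrl, alpha=0.05):
    """Classical pooled two-sample t interval for the mean difference."""
    n1, n0 = len(y_treat), len(y_ctrl)
    diff = y_treat.mean() - y_ctrl.mean()
    sp2 = (
        ((y_treat - y_treat.mean()) ** 2).sum() + ((y_ctrl - y_ctrl.mean()) ** 2).sum()
    ) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    tq = stats.t.ppf(1 - alpha / 2, n1 + n0 - 2)
    return diff - tq * se, diff + tq * se, n1 + n0 - 2


def weighted_mean_difference(data):
    """Fixed-effect GLS estimate of the treatment effect for the
    stratified-intercept common-effect model: the inverse-variance
    weighted average of per-trial mean differences with weights
    n_treat * n_ctrl / n."""
    diffs, weights = [], []
    for i in range(data.K):
        mask = data.trial_index == i
        y, t = data.y_final[mask], data.treat[mask]
        diffs.append(y[t == 1].mean() - y[t == 0].mean())
        n1, n0 = (t == 1).sum(), (t == 0).sum()
        weights.append(n1 * n0 / (n1 + n0))
    diffs, weights = np.asarray(diffs), np.asarray(weights)
    return float((weights * diffs).sum() / weights.sum())
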