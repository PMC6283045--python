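"""Confidence intervals for the summary treatment effect.

Three interval constructions are offered for a fitted one-stage model:

- standard:      theta_hat +/- z_{1-a/2} sqrt(Var(theta_hat))
- Satterthwaite: theta_hat +/- t_{v;1-a/2} sqrt(Var(theta_hat))
- Kenward-Roger: theta_hat +/- t_{v;1-a/2} sqrt(Var_KR(theta_hat))

where v is the moment-matching denominator degrees of freedom and Var_KR is
the first-order bias-adjusted ("inflated") covariance.  For a single
parameter the KR and Satterthwaite moment rules coincide, so both intervals
share the same v and differ only through the adjusted variance.  The
corrections are defined for REML fits; ML fits are offered the standard
interval only.

All formulas are evaluated through the per-trial low-rank structures of the
likelihood module.  With V linear in the variance components psi, writing
P_k = -X'V^{-1}(dV/dpsi_k)V^{-1}X and
Q_kl = X'V^{-1}(dV/dpsi_k)V^{-1}(dV/dpsi_l)V^{-1}X:

- expected information: I_kl = tr(V^{-1}V_k V^{-1}V_l)/2 for ML, with the
  REML projection replacing V^{-1} by P = V^{-1} - V^{-1}X Phi X'V^{-1};
- W = I^{-1} (asymptotic covariance of the variance-component estimates);
- dPhi/dpsi_k = Phi S_k Phi with S_k = -P_k, giving the Satterthwaite
  denominator g'Wg for g_k = [Phi S_k Phi]_(theta,theta);
- Phi_A = Phi + 2 Phi [ sum_kl W_kl (Q_kl - P_k Phi P_l) ] Phi  (the
  second-derivative terms vanish because V is linear in psi).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import DesignBundle
from .exceptions import InferenceError, UsageError
from .fit import FitResult
from .likelihood import block_state

__all__ = [
    "CIResult",
    "varcomp_information",
    "ci_standard",
    "ci_satterthwaite",
    "ci_kenward_roger",
    "corrected_cis",
    "coverage_indicator",
]

logger = logging.getLogger(__name__)

_COND_MAX = 1e12


@dataclass
class CIResult:
    """One confidence interval for theta.

    ``df`` is +inf for the standard normal interval and the (unrounded)
    moment-matching degrees of freedom otherwise.  ``var_used`` is the
    model-based Var(theta_hat) for the standard and Satterthwaite intervals
    and the KR-adjusted variance for the KR interval.  ``note`` carries
    non-fatal diagnostics (e.g. a KR adjustment below the unadjusted
    variance, or a variance component dropped at the boundary).
    """

    method: str
    lower: float
    upper: float
    df: float
    var_used: float
    alpha: float
    estimate: float
    note: str | None = None


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise InferenceError("alpha must lie strictly inside (0, 1)")


class _Structures:
    """Per-fit derivative structures shared by W, Satterthwaite and KR."""

    def __init__(self, fit: FitResult, design: DesignBundle):
        if not fit.converged:
            raise InferenceError("fit did not converge; no corrected interval")
        psi = np.asarray(fit.varcomp, dtype=float)
        if psi[0] <= 0.0:
            raise InferenceError(
                "residual variance estimate is on the zero boundary; "
                "the covariance of the variance components is undefined"
            )
        self.q = design.q
        self.theta = design.theta_index
        st = block_state(psi, design, fit.spec.estimation)
        self.Phi = st.fixed_cov
        A, J, F, H = design.A, st.J, st.F, design.H
        sigma2 = st.sigma2
        n = design.n

        J2 = F.transpose(0, 2, 1) @ H @ F        # B'V^-2 B
        J3 = F.transpose(0, 2, 1) @ J @ F        # B'V^-3 B
        trV1 = float(((n - st.trKG) / sigma2).sum())
        trV2 = float(((n - 2 * st.trKG + st.trKGKG) / sigma2**2).sum())

        q, p = self.q, design.p
        cidx = design.rand_basis                 # basis column per component k>=1
        # per-trial p-vectors u_k = A' J e_c and w_k = A' J2 e_c
        u = [np.einsum("krp,kr->kp", A, J[:, :, c]) for c in cidx]
        w = [np.einsum("krp,kr->kp", A, J2[:, :, c]) for c in cidx]

        S = np.empty((q, p, p))
        S[0] = np.einsum("krp,krs,ksq->pq", A, J2, A, optimize=True)
        for k in range(1, q):
            S[k] = np.einsum("kp,kq->pq", u[k - 1], u[k - 1])

        T = np.empty((q, q, p, p))
        T[0, 0] = np.einsum("krp,krs,ksq->pq", A, J3, A, optimize=True)
        for k in range(1, q):
            T0k = np.einsum("kp,kq->pq", w[k - 1], u[k - 1])
            T[0, k] = T0k
            T[k, 0] = T0k.T
            for l in range(1, q):
                jcd = J[:, cidx[k - 1], cidx[l - 1]]
                T[k, l] = np.einsum("k,kp,kq->pq", jcd, u[k - 1], u[l - 1])

        Tr = np.empty((q, q))
        Tr[0, 0] = trV2
        for k in range(1, q):
            v = float(J2[:, cidx[k - 1], cidx[k - 1]].sum())
            Tr[0, k] = Tr[k, 0] = v
            for l in range(1, q):
                Tr[k, l] = float((J[:, cidx[k - 1], cidx[l - 1]] ** 2).sum())

        self.S, self.T, self.Tr, self.trV1 = S, T, Tr, trV1
        self.psi = psi
        self.estimation = fit.spec.estimation
        self.note = None

        # expected information (REML-projected when estimation is REML)
        info = 0.5 * Tr.copy()
        if self.estimation == "REML":
            Phi = self.Phi
            for k in range(q):
                for l in range(q):
                    mid = np.trace(Phi @ (T[k, l] + T[l, k]))
                    tail = np.trace(Phi @ S[k] @ Phi @ S[l])
                    info[k, l] += 0.5 * (-mid + tail)
        info = 0.5 * (info + info.T)
        self.info = info
        self.W = self._invert_information(info)

    def _invert_information(self, info: np.ndarray) -> np.ndarray:
        q = self.q
        if np.linalg.cond(info) < _COND_MAX:
            return np.linalg.inv(info)
        # retain boundary components only while the information is invertible
        keep = [k for k in range(q) if not (k > 0 and self.psi[k] == 0.0)]
        dropped = sorted(set(range(q)) - set(keep))
        if dropped:
            logger.warning(
                "information matrix singular; dropping boundary variance "
                "component(s) %s from the correction", dropped
            )
            self.note = f"boundary component(s) {dropped} dropped from W"
        sub = info[np.ix_(keep, keep)]
        if not keep or np.linalg.cond(sub) >= _COND_MAX:
            raise InferenceError(
                "singular variance-component information; use the standard CI"
            )
        W = np.zeros((q, q))
        W[np.ix_(keep, keep)] = np.linalg.inv(sub)
        return W

    # -- derived quantities ----------------------------------------------
    def satterthwaite_df(self) -> float:
        Phi, S, W, t = self.Phi, self.S, self.W, self.theta
        phi_t = Phi[t, t]
        g = np.array([(Phi @ S[k] @ Phi)[t, t] for k in range(self.q)])
        den = float(g @ W @ g)
        if not (den > 0.0) or not math.isfinite(den):
            raise InferenceError("non-positive Satterthwaite denominator")
        df = 2.0 * phi_t**2 / den
        if not (df > 0.0) or not math.isfinite(df):
            raise InferenceError("degrees of freedom are not finite and positive")
        return df

    def kr_adjusted_variance(self) -> float:
        Phi, S, T, W = self.Phi, self.S, self.T, self.W
        q = self.q
        Lam = np.zeros_like(Phi)
        for k in range(q):
            for l in range(q):
                if W[k, l] == 0.0:
                    continue
                Qs = 0.5 * (T[k, l] + T[l, k])
                Lam += W[k, l] * (Qs - S[k] @ Phi @ S[l])
        Phi_A = Phi + 2.0 * Phi @ Lam @ Phi
        return float(Phi_A[self.theta, self.theta])


def varcomp_information(fit: FitResult, design: DesignBundle) -> np.ndarray:
    """Asymptotic covariance W of the variance-component estimates.

    W is the inverse of the expected (RE)ML information of
    (sigma2[, tau2][, tau_beta2]) at the estimates, assembled from per-trial
    blocks.  Components estimated exactly at the zero boundary are retained
    using the one-sided curvature there; if that leaves the information
    singular they are dropped (zero rows/columns in W) with a warning.
    """
    return _Structures(fit, design).W


def ci_standard(fit: FitResult, alpha: float = 0.05) -> CIResult:
    """Large-sample normal interval using the model-based Var(theta_hat)."""
    _check_alpha(alpha)
    if not fit.converged:
        raise InferenceError("fit did not converge; no interval available")
    half = stats.norm.ppf(1.0 - alpha / 2.0) * math.sqrt(fit.var_theta)
    return CIResult(
        method="standard",
        lower=fit.theta_hat - half,
        upper=fit.theta_hat + half,
        df=math.inf,
        var_used=fit.var_theta,
        alpha=alpha,
        estimate=fit.theta_hat,
    )


def _require_reml(fit: FitResult) -> None:
    if fit.spec.estimation != "REML":
        raise UsageError("small-sample corrections implemented for REML fits only")


def ci_satterthwaite(
    fit: FitResult, design: DesignBundle, alpha: float = 0.05
) -> CIResult:
    """t interval with moment-matching degrees of freedom and the
    unadjusted variance."""
    _check_alpha(alpha)
    _require_reml(fit)
    s = _Structures(fit, design)
    return _satterthwaite_from(s, fit, alpha)


def _satterthwaite_from(s: _Structures, fit: FitResult, alpha: float) -> CIResult:
    df = s.satterthwaite_df()
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * math.sqrt(fit.var_theta)
    return CIResult(
        method="satterthwaite",
        lower=fit.theta_hat - half,
        upper=fit.theta_hat + half,
        df=df,
        var_used=fit.var_theta,
        alpha=alpha,
        estimate=fit.theta_hat,
        note=s.note,
    )


def ci_kenward_roger(
    fit: FitResult, design: DesignBundle, alpha: float = 0.05
) -> CIResult:
    """t interval with the first-order KR bias-adjusted variance."""
    _check_alpha(alpha)
    _require_reml(fit)
    s = _Structures(fit, design)
    return _kr_from(s, fit, alpha)


def _kr_from(s: _Structures, fit: FitResult, alpha: float) -> CIResult:
    var_kr = s.kr_adjusted_variance()
    note = s.note
    if var_kr < fit.var_theta:
        note = ((note + "; ") if note else "") + "KR variance below unadjusted variance"
    if var_kr < 0.0:
        raise InferenceError("negative KR-adjusted variance")
    df = s.satterthwaite_df()  # identical moment rule for a single parameter
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * math.sqrt(var_kr)
    return CIResult(
        method="kr",
        lower=fit.theta_hat - half,
        upper=fit.theta_hat + half,
        df=df,
        var_used=var_kr,
        alpha=alpha,
        estimate=fit.theta_hat,
        note=note,
    )


def corrected_cis(
    fit: FitResult, design: DesignBundle, alpha: float = 0.05
) -> tuple[CIResult, CIResult]:
    """(Satterthwaite, KR) intervals sharing one set of derivative
    structures — the engine's fast path."""
    _check_alpha(alpha)
    _require_reml(fit)
    s = _Structures(fit, design)
    return _satterthwaite_from(s, fit, alpha), _kr_from(s, fit, alpha)


def coverage_indicator(ci: CIResult, theta_true: float) -> int:
    """1 iff the closed interval [lower, upper] contains theta_true."""
    return int(ci.lower <= theta_true <= ci.upper)
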