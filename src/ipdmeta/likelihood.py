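"""Block-structured Gaussian marginal likelihood for one-stage IPD models.

For variance components psi = (sigma2[, tau2][, tau_beta2]) the marginal
covariance of trial i is

    V_i = sigma2 * I + sum_k d_k c_ik c_ik'

with each direction c_ik a column of the trial basis B_i (ones or treatment
indicator).  Woodbury/determinant-lemma identities reduce every quantity to
r x r algebra on the Gram matrices stored in a
:class:`~ipdmeta.dataset.DesignBundle`:

    V_i^{-1}            = (I - U_i K_i U_i') / sigma2,
    K_i                 = (sigma2 D^{-1} + U_i' U_i)^{-1},
    log|V_i|            = n_i log sigma2 + log|I + (U_i'U_i) D / sigma2|,

where U_i collects the active random-effect directions (those with d_k > 0)
and D their variances.  The cost of one likelihood evaluation is therefore
independent of the number of participants; only the one-off construction of
the bundle is linear in n.

The analytic gradient of the profiled criterion uses that the GLS fixed
effects are stationary points of the Gaussian log-density, so

    d l / d psi_k = -[ tr(V^{-1} V_k) - r' V^{-1} V_k V^{-1} r ] / 2

at the plugged-in residuals r, plus tr(Phi S_k)/2 for REML with
S_k = X'V^{-1} V_k V^{-1} X and Phi = (X'V^{-1}X)^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .dataset import DesignBundle
from .exceptions import FittingError

__all__ = ["marginal_loglik", "block_state"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class BlockState:
    """Interior quantities of one likelihood evaluation, reused by the
    information-matrix and Kenward-Roger computations.

    ``J``  (K, r, r): restricted inverses  B_i' V_i^{-1} B_i
    ``F``  (K, r, r): maps with  V_i^{-1} B_i = B_i F_i
    ``vy`` (K, r):    projections B_i' V_i^{-1} y_i
    """

    criterion: float
    beta: np.ndarray
    fixed_cov: np.ndarray | None
    xtvix: np.ndarray
    J: np.ndarray
    F: np.ndarray
    vy: np.ndarray
    ytviy: float
    trKG: np.ndarray
    trKGKG: np.ndarray
    sigma2: float
    grad: np.ndarray | None = None


def _block_core(varcomp: np.ndarray, design: DesignBundle):
    """Shared Woodbury algebra on the active random-effect directions."""
    sigma2 = float(varcomp[0])
    if not sigma2 > 0.0:
        raise FittingError("sigma2 must be strictly positive")
    d = np.asarray(varcomp[1:], dtype=float)
    if (d < 0).any():
        raise FittingError("variance components must be non-negative")

    K_tr = design.K
    H, by = design.H, design.by
    r = design.r
    active = np.flatnonzero(d > 0)
    s = active.size

    if s == 0:
        J = H / sigma2
        F = np.broadcast_to(np.eye(r) / sigma2, (K_tr, r, r)).copy()
        vy = by / sigma2
        ytviy = float(design.yty.sum() / sigma2)
        logdetV = float((design.n * np.log(sigma2)).sum())
        z = np.zeros(K_tr)
        return sigma2, None, None, J, F, vy, ytviy, logdetV, z, z

    idx = design.rand_basis[active]
    dact = d[active]
    G = H[:, idx[:, None], idx[None, :]]                      # (K, s, s)
    C = np.diag(sigma2 / dact)[None, :, :] + G
    Kmat = np.linalg.inv(C)                                    # (K, s, s)
    HE = H[:, :, idx]                                          # (K, r, s)
    J = (H - HE @ Kmat @ HE.transpose(0, 2, 1)) / sigma2

    # F_i = (I - E K E'H)/sigma2 with E the basis-selection columns
    EKEH = np.zeros((K_tr, r, r))
    EKEH[:, idx, :] = Kmat @ HE.transpose(0, 2, 1)
    F = (np.eye(r)[None, :, :] - EKEH) / sigma2

    bu = by[:, idx]                                            # (K, s)
    Kbu = (Kmat @ bu[..., None])[..., 0]
    vy = (by - (HE @ Kbu[..., None])[..., 0]) / sigma2
    ytviy = float((design.yty - (bu * Kbu).sum(axis=1)).sum() / sigma2)

    Ms = np.eye(s)[None, :, :] + G * (dact / sigma2)[None, None, :]
    sign, logdet = np.linalg.slogdet(Ms)
    if (sign <= 0).any():
        raise FittingError("non-positive-definite marginal covariance")
    logdetV = float((design.n * np.log(sigma2)).sum() + logdet.sum())

    KG = Kmat @ G
    trKG = np.einsum("kss->k", KG)
    trKGKG = np.einsum("kst,kts->k", KG, KG)
    return sigma2, idx, Kmat, J, F, vy, ytviy, logdetV, trKG, trKGKG


def block_state(
    varcomp,
    design: DesignBundle,
    estimation: str = "ML",
    need_cov: bool = True,
    need_grad: bool = False,
) -> BlockState:
    """Evaluate the profiled (RE)ML criterion and keep the interior algebra.

    Fixed effects are profiled out at their GLS solution
    ``beta = (X'V^{-1}X)^{-1} X'V^{-1} y``; the returned criterion is the
    Gaussian marginal log-likelihood at that solution, minus
    ``log|X'V^{-1}X| / 2`` for REML.  ``need_grad`` additionally fills the
    analytic gradient with respect to the variance components.
    """
    varcomp = np.asarray(varcomp, dtype=float)
    sigma2, idx, Kmat, J, F, vy, ytviy, logdetV, trKG, trKGKG = _block_core(
        varcomp, design
    )

    A = design.A
    JA = J @ A                                                  # (K, r, p)
    xtvix = np.tensordot(A, JA, axes=([0, 1], [0, 1]))
    xtviy = np.tensordot(vy, A, axes=([0, 1], [0, 1]))
    try:
        cho = linalg.cho_factor(xtvix)
        beta = linalg.cho_solve(cho, xtviy)
        logdet_xtvix = 2.0 * float(np.log(np.diag(cho[0])).sum())
    except linalg.LinAlgError as exc:
        raise FittingError(f"singular GLS system (rank-deficient design): {exc}") from exc
    fixed_cov = linalg.cho_solve(cho, np.eye(design.p)) if need_cov else None

    quad = ytviy - float(xtviy @ beta)
    crit = -0.5 * (design.n_total * _LOG2PI + logdetV + quad)
    if estimation == "REML":
        crit -= 0.5 * logdet_xtvix

    grad = None
    if need_grad:
        q = design.q
        H, by, yty, n = design.H, design.by, design.yty, design.n
        Abeta = (A @ beta[:, None])[..., 0]                     # (K, r)
        HAb = (H @ Abeta[..., None])[..., 0]
        w = by - HAb                                            # B' residual
        rr = yty - 2.0 * (Abeta * by).sum(axis=1) + (Abeta * HAb).sum(axis=1)
        vr = (F.transpose(0, 2, 1) @ w[..., None])[..., 0]      # B'V^{-1} r

        grad = np.empty(q)
        # sigma2 direction: tr(V^{-1}) - ||V^{-1} r||^2
        trV1 = float(((n - trKG) / sigma2).sum())
        if idx is None:
            quad_s = float(rr.sum()) / sigma2**2
        else:
            wu = w[:, idx]
            Kwu = (Kmat @ wu[..., None])[..., 0]
            G = H[:, idx[:, None], idx[None, :]]
            GKwu = (G @ Kwu[..., None])[..., 0]
            quad_s = float(
                (rr - 2.0 * (wu * Kwu).sum(axis=1) + (Kwu * GKwu).sum(axis=1)).sum()
            ) / sigma2**2
        grad[0] = -0.5 * (trV1 - quad_s)
        for k in range(1, q):
            c = design.rand_basis[k - 1]
            grad[k] = -0.5 * (float(J[:, c, c].sum()) - float((vr[:, c] ** 2).sum()))

        if estimation == "REML":
            J2 = F.transpose(0, 2, 1) @ H @ F                   # B'V^{-2}B
            S0 = np.tensordot(A, J2 @ A, axes=([0, 1], [0, 1]))
            grad[0] += 0.5 * float(np.trace(linalg.cho_solve(cho, S0)))
            for k in range(1, q):
                # S_k = sum_i (A_i' J_i e_c)(A_i' J_i e_c)'
                c = design.rand_basis[k - 1]
                ui = np.einsum("kr,krp->kp", J[:, :, c], A)
                Sk = ui.T @ ui
                grad[k] += 0.5 * float(np.trace(linalg.cho_solve(cho, Sk)))

    return BlockState(
        criterion=float(crit),
        beta=beta,
        fixed_cov=fixed_cov,
        xtvix=xtvix,
        J=J,
        F=F,
        vy=vy,
        ytviy=ytviy,
        trKG=trKG,
        trKGKG=trKGKG,
        sigma2=sigma2,
        grad=grad,
    )


def marginal_loglik(varcomp, design: DesignBundle, estimation: str = "ML"):
    """Profiled marginal (RE)ML criterion with GLS fixed effects.

    Parameters
    ----------
    varcomp : array-like, length q
        Variance components in bundle order (sigma2 first).
    design : DesignBundle
    estimation : {"ML", "REML"}

    Returns
    -------
    (criterion, gls_fixed_effects, fixed_cov)
        ``criterion`` matches a dense evaluation of the Gaussian marginal
        (restricted) log-likelihood; ``fixed_cov`` is
        ``(X'V^{-1}X)^{-1}``.
    """
    st = block_state(varcomp, design, estimation)
    return st.criterion, st.beta, st.fixed_cov
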