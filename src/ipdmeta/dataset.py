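"""Participant-level containers and design construction for one-stage
individual participant data (IPD) meta-analysis of a continuous outcome.

The data model is deliberately small: an :class:`IPDDataset` holds the
participant records of ``K`` randomized trials (trial label, 0/1 treatment
indicator, final outcome, optional baseline outcome), a :class:`ModelSpec`
names one of the one-stage linear mixed models that can be fitted to it,
and :func:`build_design` compiles the pair into the per-trial sufficient
statistics (:class:`DesignBundle`) consumed by the likelihood code.

Within each trial the marginal covariance of the outcome vector is

    V_i = sigma2 * I + tau2 * t_i t_i' + tau_beta2 * 1 1'

i.e. a multiple of the identity plus at most two rank-one terms spanned by
the all-ones vector (random trial intercept) and the treatment indicator
(random treatment effect).  Every fixed-effect column of trial ``i`` also
lies in the span of {1, t_i, centred baseline}, so the whole likelihood —
and the Kenward-Roger / Satterthwaite machinery built on it — reduces to
dense algebra on r x r Gram matrices with r <= 3, independent of the number
of participants.  The bundle stores exactly those Gram-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DataError,
    DesignError,
    ValidationError,
)

__all__ = ["IPDDataset", "ModelSpec", "DesignBundle", "load_ipd", "save_ipd", "build_design"]

INTERCEPT_MODES = ("stratified", "random")
TREATMENT_MODES = ("random", "common")
BASELINE_MODES = ("none", "stratified", "common")
ESTIMATIONS = ("ML", "REML")


@dataclass
class IPDDataset:
    """Participant records from ``K`` randomized trials.

    Parameters
    ----------
    trial_labels : list
        Distinct trial labels in first-appearance order; trial ``i`` of the
        model is ``trial_labels[i]``.
    trial_index : ndarray of int
        Per-record trial index into ``trial_labels`` (0-based).
    treat : ndarray of int
        0/1 treatment-arm indicator per record.
    y_final : ndarray of float
        End-of-trial continuous outcome per record.
    y_baseline : ndarray of float, optional
        Pre-treatment outcome; present for all records or for none.
    """

    trial_labels: list
    trial_index: np.ndarray
    treat: np.ndarray
    y_final: np.ndarray
    y_baseline: np.ndarray | None = None

    def __post_init__(self):
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)
        self.treat = np.asarray(self.treat, dtype=np.int64)
        self.y_final = np.asarray(self.y_final, dtype=float)
        if self.y_baseline is not None:
            self.y_baseline = np.asarray(self.y_baseline, dtype=float)
        self.validate()

    # -- structural properties -------------------------------------------
    @property
    def K(self) -> int:
        """Number of trials."""
        return len(self.trial_labels)

    @property
    def n_total(self) -> int:
        return self.y_final.size

    @property
    def n_i(self) -> np.ndarray:
        """Participants per trial, in trial order."""
        return np.bincount(self.trial_index, minlength=self.K)

    @property
    def has_baseline(self) -> bool:
        return self.y_baseline is not None

    def validate(self, require_both_arms: bool = False) -> None:
        n = self.y_final.size
        if self.trial_index.size != n or self.treat.size != n:
            raise DataError("trial, treatment and outcome columns differ in length")
        if self.K < 1:
            raise ValidationError("dataset must contain at least one trial")
        if self.trial_index.min(initial=0) < 0 or (
            n and self.trial_index.max() >= self.K
        ):
            raise ValidationError("trial index out of range")
        if not np.isin(self.treat, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(self.treat, (0, 1)))[0])
            raise DataError(f"non-binary treatment value at row {bad}")
        if not np.isfinite(self.y_final).all():
            bad = int(np.flatnonzero(~np.isfinite(self.y_final))[0])
            raise DataError(f"missing or non-numeric outcome at row {bad}")
        if self.y_baseline is not None and not np.isfinite(self.y_baseline).all():
            bad = int(np.flatnonzero(~np.isfinite(self.y_baseline))[0])
            raise DataError(f"missing or non-numeric baseline at row {bad}")
        counts = self.n_i
        if (counts < 2).any():
            lab = self.trial_labels[int(np.argmax(counts < 2))]
            raise ValidationError(f"trial {lab!r} has fewer than 2 participants")
        if require_both_arms:
            self.require_both_arms()

    def require_both_arms(self) -> None:
        """Raise unless every trial has at least one record in each arm."""
        treated = np.bincount(self.trial_index, weights=self.treat, minlength=self.K)
        single = (treated == 0) | (treated == self.n_i)
        if single.any():
            labels = [str(self.trial_labels[i]) for i in np.flatnonzero(single)]
            raise ValidationError(
                "single-arm trial(s) not usable for a treatment-effect model: "
                + ", ".join(labels)
            )

    # -- conversion -------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": [self.trial_labels[i] for i in self.trial_index],
                "treat": self.treat,
                "y_final": self.y_final,
            }
        )
        if self.y_baseline is not None:
            df["y_baseline"] = self.y_baseline
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trial_col: str = "trial",
        treat_col: str = "treat",
        outcome_col: str = "y_final",
        baseline_col: str | None = None,
        require_both_arms: bool = True,
    ) -> "IPDDataset":
        for col in (trial_col, treat_col, outcome_col):
            if col not in df.columns:
                raise ConfigurationError(f"column {col!r} not found in input")
        if baseline_col is not None and baseline_col not in df.columns:
            raise ConfigurationError(f"baseline column {baseline_col!r} not found in input")

        labels = list(pd.unique(df[trial_col]))
        index_of = {lab: i for i, lab in enumerate(labels)}
        trial_index = df[trial_col].map(index_of).to_numpy()

        treat_raw = pd.to_numeric(df[treat_col], errors="coerce")
        if treat_raw.isna().any():
            raise DataError(
                f"non-numeric treatment value at row {int(treat_raw.isna().idxmax())}"
            )
        y_raw = pd.to_numeric(df[outcome_col], errors="coerce")
        if y_raw.isna().any():
            raise DataError(
                f"non-numeric outcome value at row {int(y_raw.isna().idxmax())}"
            )

        baseline = None
        if baseline_col is not None:
            b_raw = pd.to_numeric(df[baseline_col], errors="coerce")
            n_missing = int(b_raw.isna().sum())
            if n_missing == len(b_raw):
                baseline = None
            elif n_missing > 0:
                raise DataError(
                    f"baseline present for only {len(b_raw) - n_missing} of "
                    f"{len(b_raw)} rows; it must be present for all or none"
                )
            else:
                baseline = b_raw.to_numpy()

        ds = cls(labels, trial_index, treat_raw.to_numpy(), y_raw.to_numpy(), baseline)
        if require_both_arms:
            ds.require_both_arms()
        return ds


def load_ipd(
    path,
    trial_col: str = "trial",
    treat_col: str = "treat",
    outcome_col: str = "y_final",
    baseline_col: str | None = None,
    require_both_arms: bool = True,
) -> IPDDataset:
    """Read a delimited IPD file (header row, comma-separated).

    Trial labels are mapped to contiguous model indices in first-appearance
    order.  ``require_both_arms`` controls the single-arm-trial check, which
    only matters when a treatment-effect model will be fitted.
    """
    df = pd.read_csv(path)
    return IPDDataset.from_dataframe(
        df, trial_col, treat_col, outcome_col, baseline_col, require_both_arms
    )


def save_ipd(data: IPDDataset, path) -> None:
    """Write a dataset back to CSV in the canonical column layout."""
    data.to_dataframe().to_csv(path, index=False)


@dataclass
class ModelSpec:
    """Specification of a one-stage IPD meta-analysis linear mixed model.

    ``intercept_mode`` chooses between a separate fixed intercept per trial
    ("stratified") and normally distributed trial intercepts with variance
    tau_beta2 ("random").  ``treatment_mode`` chooses between trial-specific
    true effects N(theta, tau2) ("random") and a single shared effect
    ("common", no tau2 parameter).  A single residual variance sigma2 is
    shared by all trials.
    """

    intercept_mode: str = "stratified"
    treatment_mode: str = "random"
    baseline_adjustment: str = "none"
    estimation: str = "REML"
    alpha: float = 0.05
    max_iter: int = 100
    rel_tol: float = 1e-8

    def __post_init__(self):
        if self.intercept_mode not in INTERCEPT_MODES:
            raise ConfigurationError(f"unknown intercept_mode {self.intercept_mode!r}")
        if self.treatment_mode not in TREATMENT_MODES:
            raise ConfigurationError(f"unknown treatment_mode {self.treatment_mode!r}")
        if self.baseline_adjustment not in BASELINE_MODES:
            raise ConfigurationError(
                f"unknown baseline_adjustment {self.baseline_adjustment!r}"
            )
        if self.estimation not in ESTIMATIONS:
            raise ConfigurationError(f"unknown estimation {self.estimation!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie strictly inside (0, 1)")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


@dataclass
class DesignBundle:
    """Per-trial sufficient statistics for the block marginal likelihood.

    Each trial contributes a basis ``B_i`` of at most three columns
    (ones, treatment indicator, trial-centred baseline).  All quantities the
    fitter and the small-sample corrections need are expressible through:

    - ``H``      (K, r, r)  Gram matrices ``B_i' B_i``
    - ``A``      (K, r, p)  map from basis rows to global fixed-effect columns,
                            so the trial's fixed design is ``X_i = B_i A_i``
    - ``by``     (K, r)     projections ``B_i' y_i``
    - ``yty``    (K,)       squared norms ``y_i' y_i``
    - ``n``      (K,)       participants per trial

    ``rand_basis`` holds, per estimated random-effect variance (after
    sigma2), the basis column whose outer product it scales: the treatment
    column for tau2, the ones column for tau_beta2.  The treatment effect is
    always the last fixed-effect column (``theta_index == p - 1``).
    """

    K: int
    n: np.ndarray
    H: np.ndarray
    A: np.ndarray
    by: np.ndarray
    yty: np.ndarray
    p: int
    varcomp_names: list
    rand_basis: np.ndarray
    fixed_names: list
    # per-trial two-group summaries used for method-of-moments starting values
    n_treat: np.ndarray = field(default=None, repr=False)
    mean_ctrl: np.ndarray = field(default=None, repr=False)
    mean_treat: np.ndarray = field(default=None, repr=False)
    ss_within: np.ndarray = field(default=None, repr=False)

    @property
    def q(self) -> int:
        return len(self.varcomp_names)

    @property
    def r(self) -> int:
        return self.H.shape[1]

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def theta_index(self) -> int:
        return self.p - 1


def build_design(data: IPDDataset, spec: ModelSpec) -> DesignBundle:
    """Compile a dataset/model pair into per-trial sufficient statistics.

    Fixed-effect column order is deterministic: trial intercepts (or the
    single shared intercept), baseline coefficients (if requested), and the
    treatment effect last.  Baseline columns are centred at each trial's own
    baseline mean, so they sum to zero within trial.
    """
    if spec.baseline_adjustment != "none" and not data.has_baseline:
        raise ConfigurationError(
            "baseline adjustment requested but the dataset has no baseline column"
        )
    data.require_both_arms()

    K = data.K
    use_baseline = spec.baseline_adjustment != "none"
    r = 3 if use_baseline else 2

    n_int = K if spec.intercept_mode == "stratified" else 1
    if not use_baseline:
        n_base = 0
    else:
        n_base = K if spec.baseline_adjustment == "stratified" else 1
    p = n_int + n_base + 1

    H = np.zeros((K, r, r))
    A = np.zeros((K, r, p))
    by = np.zeros((K, r))
    yty = np.zeros(K)
    n = np.zeros(K, dtype=np.int64)
    m = np.zeros(K, dtype=np.int64)
    mean_c = np.zeros(K)
    mean_t = np.zeros(K)
    ssw = np.zeros(K)

    for i in range(K):
        rows = np.flatnonzero(data.trial_index == i)
        t = data.treat[rows].astype(float)
        y = data.y_final[rows]
        ni, mi = rows.size, int(t.sum())
        n[i], m[i] = ni, mi
        cols = [np.ones(ni), t]
        if use_baseline:
            b = data.y_baseline[rows]
            b = b - b.mean()
            if float(b @ b) <= 1e-12 * ni:
                raise DesignError(
                    f"baseline is constant within trial {data.trial_labels[i]!r}; "
                    "the baseline coefficient is not identifiable"
                )
            cols.append(b)
        B = np.column_stack(cols)
        H[i] = B.T @ B
        by[i] = B.T @ y
        yty[i] = y @ y
        # fixed-effect map: intercept, baseline term(s), treatment (last)
        A[i, 0, i if spec.intercept_mode == "stratified" else 0] = 1.0
        if use_baseline:
            A[i, 2, n_int + (i if spec.baseline_adjustment == "stratified" else 0)] = 1.0
        A[i, 1, p - 1] = 1.0

        yt = y[t == 1]
        yc = y[t == 0]
        mean_t[i], mean_c[i] = yt.mean(), yc.mean()
        ssw[i] = ((yt - yt.mean()) ** 2).sum() + ((yc - yc.mean()) ** 2).sum()

    varcomp_names = ["sigma2"]
    rand_basis = []
    if spec.treatment_mode == "random":
        varcomp_names.append("tau2")
        rand_basis.append(1)  # treatment column of the basis
    if spec.intercept_mode == "random":
        varcomp_names.append("tau_beta2")
        rand_basis.append(0)  # ones column of the basis

    if spec.intercept_mode == "stratified":
        fixed_names = [f"beta[{lab}]" for lab in data.trial_labels]
    else:
        fixed_names = ["beta"]
    if use_baseline:
        if spec.baseline_adjustment == "stratified":
            fixed_names += [f"lambda[{lab}]" for lab in data.trial_labels]
        else:
            fixed_names += ["lambda"]
    fixed_names.append("theta")

    return DesignBundle(
        K=K,
        n=n,
        H=H,
        A=A,
        by=by,
        yty=yty,
        p=p,
        varcomp_names=varcomp_names,
        rand_basis=np.asarray(rand_basis, dtype=np.int64),
        fixed_names=fixed_names,
        n_treat=m,
        mean_ctrl=mean_c,
        mean_treat=mean_t,
        ss_within=ssw,
    )
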