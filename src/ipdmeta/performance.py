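"""Performance summaries of the simulation replicates.

For each (scenario, variant, model, estimation, CI method) cell the
summaries are, with R converged replicates and true effect theta:

- mean percentage bias of theta_hat:   100 * (mean(theta_hat) - theta) / theta
- median percentage bias of tau2_hat:  100 * (median(tau2_hat) - tau2) / tau2
  (absent when the true tau2 is 0 or the model has no tau2)
- empirical SE:  sample SD of theta_hat (divisor R - 1)
- MSE:           mean((theta_hat - theta)^2)  (divisor R), which satisfies
                 mse = bias_abs^2 + emp_se^2 * (R - 1) / R exactly
- coverage:      100 * mean(coverage indicator), per CI method
- Monte-Carlo SE of coverage: 100 * sqrt(c (1 - c) / R)

Estimate-based metrics condition on converged fits; the convergence
percentage itself is computed over all replicates.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .dgm import ScenarioConfig

__all__ = ["summarize", "mc_error_coverage", "render_tables"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "scenario_id",
    "dgm_variant",
    "model",
    "estimation",
    "ci_method",
    "mean_pct_bias_theta",
    "median_pct_bias_tau2",
    "emp_se",
    "mse",
    "coverage_pct",
    "mc_se_coverage",
    "convergence_pct",
    "n_converged",
    "n_reps",
    "mean_runtime",
]


def mc_error_coverage(p: float, n_reps: int) -> float:
    """Monte-Carlo standard error, in percentage points, of an observed
    coverage proportion ``p`` over ``n_reps`` replicates."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return 100.0 * math.sqrt(p * (1.0 - p) / n_reps)


def summarize(table: pd.DataFrame, truth: ScenarioConfig) -> pd.DataFrame:
    """Per-cell performance metrics for one scenario's replication table."""
    if table.empty:
        raise ValueError("replication table is empty")

    rows = []
    keys = ["scenario_id", "dgm_variant", "model", "estimation", "ci_method"]
    for key_vals, grp in table.groupby(keys, sort=True):
        n_reps = len(grp)
        conv = grp[grp["converged"] == 1]
        row = dict(zip(keys, key_vals))
        row["n_reps"] = n_reps
        row["n_converged"] = len(conv)
        row["convergence_pct"] = 100.0 * len(conv) / n_reps
        row["mean_runtime"] = float(grp["runtime_seconds"].mean())
        if len(conv) == 0:
            logger.warning("no converged replicates in cell %s", key_vals)
            for k in ("mean_pct_bias_theta", "median_pct_bias_tau2", "emp_se",
                      "mse", "coverage_pct", "mc_se_coverage"):
                row[k] = math.nan
            rows.append(row)
            continue

        th = conv["theta_hat"].to_numpy()
        bias_abs = float(th.mean() - truth.theta)
        row["mean_pct_bias_theta"] = 100.0 * bias_abs / truth.theta
        row["emp_se"] = float(th.std(ddof=1)) if len(th) > 1 else 0.0
        row["mse"] = float(((th - truth.theta) ** 2).mean())

        if truth.tau2 > 0 and conv["tau2_hat"].notna().any():
            med = float(np.median(conv["tau2_hat"].to_numpy()))
            row["median_pct_bias_tau2"] = 100.0 * (med - truth.tau2) / truth.tau2
        else:
            row["median_pct_bias_tau2"] = math.nan

        cov = conv["covered"].dropna()
        if len(cov):
            c = float(cov.mean())
            row["coverage_pct"] = 100.0 * c
            row["mc_se_coverage"] = mc_error_coverage(c, len(cov))
        else:
            row["coverage_pct"] = math.nan
            row["mc_se_coverage"] = math.nan
        rows.append(row)

    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def render_tables(summaries: pd.DataFrame, out_dir, plot: bool = False) -> dict:
    """Write wide-format result files from (concatenated) summaries.

    Produces, per variant present: a treatment-effect bias table and a tau2
    bias table (scenario rows x model/estimation columns), a coverage table
    (scenario rows x model/estimation/CI-method columns), and a convergence
    table.  Optionally draws a coverage dot plot.  Returns the paths
    written, keyed by short names.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def pivot(df, value, cols):
        if df.empty:
            return pd.DataFrame(columns=["scenario_id"])
        wide = df.pivot_table(
            index=["scenario_id", "dgm_variant"], columns=cols, values=value,
            sort=False,
        )
        wide.columns = ["_".join(map(str, c)) if isinstance(c, tuple) else str(c)
                        for c in wide.columns]
        return wide.reset_index()

    base = summaries[summaries["ci_method"] == "standard"] if not summaries.empty else summaries
    for name, value, frame, cols in [
        ("bias_theta", "mean_pct_bias_theta", base, ["model", "estimation"]),
        ("bias_tau2", "median_pct_bias_tau2", base, ["model", "estimation"]),
        ("coverage", "coverage_pct", summaries, ["model", "estimation", "ci_method"]),
        ("convergence", "convergence_pct", base, ["model", "estimation"]),
    ]:
        path = out_dir / f"{name}.csv"
        pivot(frame, value, cols).to_csv(path, index=False)
        paths[name] = path

    if plot and not summaries.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 0.5 + 0.3 * summaries["scenario_id"].nunique()))
        labels = []
        for i, (sid, grp) in enumerate(summaries.groupby("scenario_id", sort=False)):
            labels.append(sid)
            for _, r in grp.iterrows():
                ax.plot(r["coverage_pct"], i, "o", ms=4, alpha=0.6)
        ax.axvline(95.0, color="k", lw=0.8, ls="--")
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("coverage of the 95% CI (%)")
        fig.tight_layout()
        path = out_dir / "coverage.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths["coverage_plot"] = path

    return paths
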