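"""Replication engine for the simulation study.

One replicate = one generated IPD dataset, four model fits (stratified and
random intercept, each by ML and REML), and up to eight confidence-interval
rows: the standard interval from each ML fit, and the standard,
Kenward-Roger and Satterthwaite intervals from each REML fit.  Under the
common-effect variant the same combinations are run with common-effect
model specifications.  Every failure mode (non-convergence, an inference
correction that cannot be computed) is recorded as an outcome, never
raised.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dataset import ModelSpec, build_design
from .dgm import ScenarioConfig, generate_dataset, replicate_rng
from .exceptions import InferenceError
from .fit import fit
from .inference import ci_standard, corrected_cis, coverage_indicator

__all__ = ["run_replication", "run_scenario", "RECORD_COLUMNS"]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "scenario_id",
    "dgm_variant",
    "rep_index",
    "model",
    "estimation",
    "ci_method",
    "theta_hat",
    "ci_lower",
    "ci_upper",
    "covered",
    "tau2_hat",
    "tau_beta2_hat",
    "sigma2_hat",
    "converged",
    "n_iter",
    "runtime_seconds",
]


def _record(config, rep_index, res, ci_method, ci):
    row = {
        "scenario_id": config.scenario_id,
        "dgm_variant": config.dgm_variant,
        "rep_index": rep_index,
        "model": res.spec.intercept_mode,
        "estimation": res.spec.estimation,
        "ci_method": ci_method,
        "theta_hat": res.theta_hat if res.converged else math.nan,
        "ci_lower": math.nan,
        "ci_upper": math.nan,
        "covered": math.nan,
        "tau2_hat": res.tau2_hat if res.converged else math.nan,
        "tau_beta2_hat": (
            res.tau_beta2_hat
            if (res.converged and res.tau_beta2_hat is not None)
            else math.nan
        ),
        "sigma2_hat": res.sigma2_hat if res.converged else math.nan,
        "converged": int(res.converged),
        "n_iter": res.n_iter,
        "runtime_seconds": res.runtime_seconds,
    }
    if res.tau2_hat is None:
        row["tau2_hat"] = math.nan
    if ci is not None:
        row["ci_lower"] = ci.lower
        row["ci_upper"] = ci.upper
        row["covered"] = coverage_indicator(ci, config.theta)
    return row


def run_replication(
    config: ScenarioConfig, rep_index: int, master_seed: int, alpha: float = 0.05
) -> list:
    """Generate one dataset and produce its (up to) eight CI records."""
    rng = replicate_rng(master_seed, config.scenario_id, config.dgm_variant, rep_index)
    data, _truth = generate_dataset(config, rng)
    treatment_mode = "common" if config.dgm_variant == "normal_common" else "random"

    rows = []
    for intercept_mode in ("stratified", "random"):
        design = None
        for estimation in ("ML", "REML"):
            spec = ModelSpec(
                intercept_mode=intercept_mode,
                treatment_mode=treatment_mode,
                estimation=estimation,
                alpha=alpha,
            )
            if design is None:
                design = build_design(data, spec)
            res = fit(data, spec, design=design)

            methods = ["standard"] if estimation == "ML" else ["standard", "kr", "satterthwaite"]
            cis = dict.fromkeys(methods)
            if res.converged:
                cis["standard"] = ci_standard(res, alpha)
                if estimation == "REML":
                    try:
                        satt, kr = corrected_cis(res, design, alpha)
                        cis["satterthwaite"], cis["kr"] = satt, kr
                    except InferenceError as exc:
                        logger.debug(
                            "correction failed (%s %s rep %d): %s",
                            config.scenario_id, intercept_mode, rep_index, exc,
                        )
            for method in methods:
                rows.append(_record(config, rep_index, res, method, cis[method]))
    return rows


def run_scenario(
    config: ScenarioConfig,
    n_reps: int = 1000,
    master_seed: int = 0,
    workers: int = 1,
    out_path=None,
    alpha: float = 0.05,
    log_every: int = 100,
) -> pd.DataFrame:
    """Run ``n_reps`` replicates of one scenario.

    Results are invariant to ``workers`` because each replicate derives its
    own RNG substream from (master_seed, scenario, replicate index).  With
    ``out_path`` records are appended to CSV in chunks as replicates
    complete, and an interrupted run resumes after the last fully written
    replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    done: set = set()
    out_path = Path(out_path) if out_path is not None else None
    existing = None
    if out_path is not None and out_path.exists():
        existing = pd.read_csv(out_path)
        if len(existing):
            done = set(existing["rep_index"].astype(int).unique())

    todo = [r for r in range(n_reps) if r not in done]
    chunks = [existing] if existing is not None and len(existing) else []

    def flush(rows):
        df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        if out_path is not None:
            header = not out_path.exists()
            df.to_csv(out_path, mode="a", header=header, index=False)
        chunks.append(df)

    chunk_size = max(log_every, 1)
    for start in range(0, len(todo), chunk_size):
        batch = todo[start : start + chunk_size]
        if workers > 1:
            results = Parallel(n_jobs=workers)(
                delayed(run_replication)(config, r, master_seed, alpha) for r in batch
            )
        else:
            results = [run_replication(config, r, master_seed, alpha) for r in batch]
        flush([row for rows in results for row in rows])
        logger.info(
            "%s/%s: %d/%d replicates done",
            config.scenario_id, config.dgm_variant,
            min(start + chunk_size, len(todo)), len(todo),
        )

    table = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=RECORD_COLUMNS
    )
    return table.sort_values(["rep_index", "model", "estimation", "ci_method"],
                             kind="stable").reset_index(drop=True)
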