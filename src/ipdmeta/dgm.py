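"""Synthetic IPD generator for the simulation study.

A dataset is one IPD meta-analysis of K randomized trials with a continuous
final outcome.  Under the normal variants the outcome of participant j in
trial i is

    Y_ij = beta + u1_i + (theta + u2_i) * treat_ij + e_ij,
    u1_i ~ N(0, tau_beta2),  u2_i ~ N(0, tau2),  e_ij ~ N(0, sigma2);

the beta variant replaces beta + u1_i by a negatively skewed intercept
beta_i ~ 220 * Beta(15, 3), and the common variant fixes u2_i = 0 (a single
shared treatment effect).  Allocation is exactly balanced 1:1 within trial
(extra participant on odd sizes goes to control), and no baseline outcome
is generated: the study analyses final scores only.

The scenario grid lives in ``resources/scenarios.yaml``: 14 geometries
crossed with the three variants minus 4 inapplicable cells = 38 scenarios.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dataset import IPDDataset
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "expand_scenario_grid",
    "load_scenario",
    "draw_trial_sizes",
    "allocate_treatment",
    "generate_dataset",
    "replicate_rng",
]

DGM_VARIANTS = ("normal_random", "beta_random", "normal_common")

#: scenario ids inapplicable per variant
EXCLUSIONS = {
    "beta_random": {"C1", "C2"},
    "normal_common": {"D1", "D2"},
}


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid.

    ``size_spec`` is an ordered list of grouped trial-size rules, e.g.
    ``[{"count": 5, "kind": "uniform", "low": 30, "high": 100},
    {"count": 5, "kind": "uniform", "low": 900, "high": 1000}]``; the rules
    expand, in order, to one size per trial.  ``beta_shape``/``beta_scale``
    only matter for the beta intercept variant.
    """

    scenario_id: str
    dgm_variant: str
    K: int
    size_spec: list
    theta: float
    tau2: float
    beta_mean: float
    tau_beta2: float
    sigma2: float
    beta_shape: tuple = (15.0, 3.0)
    beta_scale: float = 220.0

    def __post_init__(self):
        if self.dgm_variant not in DGM_VARIANTS:
            raise ConfigurationError(f"unknown dgm_variant {self.dgm_variant!r}")
        if self.scenario_id in EXCLUSIONS.get(self.dgm_variant, ()):
            raise ConfigurationError(
                f"scenario {self.scenario_id!r} is not defined under "
                f"{self.dgm_variant!r}"
            )
        if self.dgm_variant == "normal_common" and self.tau2 != 0.0:
            raise ConfigurationError("the common-effect variant requires tau2 = 0")
        if self.tau2 < 0 or self.tau_beta2 < 0 or self.sigma2 < 0:
            raise ConfigurationError("variances must be non-negative")
        total = sum(int(b["count"]) for b in self.size_spec)
        if total != self.K:
            raise ConfigurationError(
                f"size rules cover {total} trials but K = {self.K}"
            )

    # -- config-file round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.scenario_id,
            "dgm_variant": self.dgm_variant,
            "K": self.K,
            "sizes": [dict(b) for b in self.size_spec],
            "theta": self.theta,
            "tau2": self.tau2,
            "beta_mean": self.beta_mean,
            "tau_beta2": self.tau_beta2,
            "sigma2": self.sigma2,
            "beta_shape": list(self.beta_shape),
            "beta_scale": self.beta_scale,
        }

    @classmethod
    def from_dict(cls, d: dict, dgm_variant: str | None = None) -> "ScenarioConfig":
        variant = d.get("dgm_variant", dgm_variant)
        tau2 = float(d["tau2"])
        if variant == "normal_common":
            tau2 = 0.0
        return cls(
            scenario_id=str(d["id"]),
            dgm_variant=variant,
            K=int(d["K"]),
            size_spec=[dict(b) for b in d["sizes"]],
            theta=float(d["theta"]),
            tau2=tau2,
            beta_mean=float(d["beta_mean"]),
            tau_beta2=float(d["tau_beta2"]),
            sigma2=float(d["sigma2"]),
            beta_shape=tuple(d.get("beta_shape", (15.0, 3.0))),
            beta_scale=float(d.get("beta_scale", 220.0)),
        )


@dataclass
class TruthRecord:
    """Trial-level draws behind one dataset (diagnostics only; never
    visible to the fitters)."""

    sizes: np.ndarray
    intercepts: np.ndarray
    u2: np.ndarray = field(default=None)


def _scenario_blocks() -> list:
    text = resources.files("ipdmeta.resources").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)["scenarios"]


def expand_scenario_grid() -> list:
    """All 38 grid cells in deterministic order: the three variants in
    declaration order, the 14 geometries in file order, minus the four
    inapplicable cells."""
    blocks = _scenario_blocks()
    grid = []
    for variant in DGM_VARIANTS:
        excluded = EXCLUSIONS.get(variant, set())
        for blk in blocks:
            if blk["id"] in excluded:
                continue
            grid.append(ScenarioConfig.from_dict(blk, dgm_variant=variant))
    return grid


def load_scenario(scenario_id: str, dgm_variant: str = "normal_random") -> ScenarioConfig:
    """Look up one scenario geometry by id under a given variant."""
    for blk in _scenario_blocks():
        if blk["id"] == scenario_id:
            return ScenarioConfig.from_dict(blk, dgm_variant=dgm_variant)
    raise ConfigurationError(f"unknown scenario {scenario_id!r}")


def replicate_rng(master_seed: int, scenario_id: str, dgm_variant: str,
                  rep_index: int) -> np.random.Generator:
    """Independent substream for one replicate.

    Streams are keyed by (master seed, scenario/variant hash, replicate), so
    every replicate is reproducible in isolation and results do not depend
    on how replicates are distributed over workers.
    """
    key = zlib.crc32(f"{scenario_id}:{dgm_variant}".encode()) & 0x7FFFFFFF
    seq = np.random.SeedSequence([int(master_seed), key, int(rep_index)])
    return np.random.default_rng(seq)


def draw_trial_sizes(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Expand the size rules to K integer trial sizes; uniform rules draw
    integers inclusively from [low, high]."""
    sizes = []
    for blk in config.size_spec:
        count = int(blk["count"])
        if blk["kind"] == "fixed":
            sizes.extend([int(blk["n"])] * count)
        elif blk["kind"] == "uniform":
            sizes.extend(rng.integers(int(blk["low"]), int(blk["high"]) + 1,
                                      size=count).tolist())
        else:
            raise ConfigurationError(f"unknown size rule kind {blk['kind']!r}")
    return np.asarray(sizes, dtype=np.int64)


def allocate_treatment(n_i: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced 1:1 allocation: floor(n/2) treated, positions
    permuted; the extra participant on odd n goes to control."""
    if n_i < 2:
        raise ValidationError("a trial needs at least 2 participants")
    t = np.zeros(n_i, dtype=np.int64)
    t[rng.permutation(n_i)[: n_i // 2]] = 1
    return t


def generate_dataset(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[IPDDataset, TruthRecord]:
    """Generate one IPD meta-analysis dataset under the scenario's variant.

    Draw order is fixed (sizes, trial intercepts, trial treatment effects,
    then per trial: allocation and residuals), so a given (config, rng
    state) always yields a bit-identical dataset.
    """
    sizes = draw_trial_sizes(config, rng)
    K = config.K

    if config.dgm_variant == "beta_random":
        intercepts = config.beta_scale * rng.beta(*config.beta_shape, size=K)
    else:
        intercepts = config.beta_mean + rng.normal(0.0, np.sqrt(config.tau_beta2), K)

    if config.dgm_variant == "normal_common":
        u2 = np.zeros(K)
    else:
        u2 = rng.normal(0.0, np.sqrt(config.tau2), K)

    labels = [f"trial_{i + 1:02d}" for i in range(K)]
    trial_index = np.repeat(np.arange(K), sizes)
    treat = np.empty(int(sizes.sum()), dtype=np.int64)
    y = np.empty(int(sizes.sum()))
    pos = 0
    sd = np.sqrt(config.sigma2)
    for i in range(K):
        n = int(sizes[i])
        t = allocate_treatment(n, rng)
        e = rng.normal(0.0, sd, n)
        treat[pos : pos + n] = t
        y[pos : pos + n] = intercepts[i] + (config.theta + u2[i]) * t + e
        pos += n

    data = IPDDataset(labels, trial_index, treat, y)
    return data, TruthRecord(sizes=sizes, intercepts=intercepts, u2=u2)
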