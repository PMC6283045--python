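"""Shared fixtures: seeded datasets and the (expensive) scenario runs
used both by the module tests and the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from ipdmeta.dataset import IPDDataset
from ipdmeta.dgm import generate_dataset, load_scenario, replicate_rng
from ipdmeta.engine import run_scenario

MASTER_SEED = 20180813
FULL_REPS = 1000


def make_balanced_dataset(K=10, n=100, theta=-9.66, beta=159.73, noise=None):
    """Deterministic balanced two-arm layout; noise=None gives exact data."""
    labels = [f"T{i + 1}" for i in range(K)]
    trial_index = np.repeat(np.arange(K), n)
    treat = np.tile(np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)], K)
    y = beta + theta * treat.astype(float)
    if noise is not None:
        y = y + noise
    return IPDDataset(labels, trial_index, treat, y)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return make_balanced_dataset()


@pytest.fixture(scope="session")
def base_dataset():
    """One seeded base-case draw with a clearly interior tau2 estimate."""
    cfg = load_scenario("Base")
    data, _ = generate_dataset(cfg, replicate_rng(5, "Base", "normal_random", 0))
    return data


@pytest.fixture(scope="session")
def small_dataset():
    """K=3, n_i=10: small enough for dense oracles."""
    cfg = load_scenario("Base")
    cfg.K = 3
    cfg.size_spec = [{"count": 3, "kind": "fixed", "n": 10}]
    data, _ = generate_dataset(cfg, replicate_rng(11, "small", "normal_random", 0))
    return data


def _scenario_run(scenario_id, variant, reps):
    cfg = load_scenario(scenario_id, variant)
    table = run_scenario(cfg, n_reps=reps, master_seed=MASTER_SEED)
    return cfg, table


@pytest.fixture(scope="session")
def base_run():
    return _scenario_run("Base", "normal_random", FULL_REPS)


@pytest.fixture(scope="session")
def b2_run():
    return _scenario_run("B2", "normal_random", FULL_REPS)


@pytest.fixture(scope="session")
def b3_run():
    return _scenario_run("B3", "normal_random", FULL_REPS)


@pytest.fixture(scope="session")
def b2a1_run():
    return _scenario_run("B2-A1", "normal_random", FULL_REPS)


@pytest.fixture(scope="session")
def common_run():
    return _scenario_run("Base", "normal_common", FULL_REPS)
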