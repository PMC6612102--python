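import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stagedex as sx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def bh_step_up_oracle(pvalues):
    """Brute-force Benjamini-Hochberg: cumulative minimum of p*n/rank."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def monotone_direction_oracle(means):
    """Brute-force strict check of every adjacent group-mean pair."""
    ups = [means[i] < means[i + 1] for i in range(len(means) - 1)]
    downs = [means[i] > means[i + 1] for i in range(len(means) - 1)]
    if all(ups):
        return "UP"
    if all(downs):
        return "DOWN"
    return "none"


@pytest.fixture(scope="session")
def balanced_cohort():
    """Small balanced simulated cohort with a mix of planted classes."""
    cfg = sx.SimConfig(
        n_genes=300,
        group_sizes=(12, 12, 12, 12, 12),
        seed=11,
    )
    dataset, truth = sx.generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def default_cohort_run():
    """Full pipeline on the default imbalanced cohort with planted effects.

    Conditions: default group sizes (50, 170, 85, 85, 6), effect_lfc=3,
    fixed seed; shared across recovery tests.
    """
    cfg = sx.SimConfig(n_genes=2000, seed=7, effect_lfc=3.0)
    result = sx.run_pipeline(sim_config=cfg)
    _, truth = sx.generate_dataset(cfg)
    return cfg, result, truth
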