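import numpy as np
import pandas as pd
import pytest

from tec_coexnet.simulate import SimulationConfig, simulate_cohort, simulate_expression


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale cohort: 8 subjects, 2 planted modules, bernoulli dropout."""
    return SimulationConfig(
        seed=11,
        n_subjects=8,
        fraction_missing=0.1,
        missingness="bernoulli",
        n_modules=2,
        module_sizes=(40, 40),
        origin_effects=(1.5, 0.0),
        activation_effects=(0.0, 1.2),
        n_background_genes=120,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    annotation = simulate_cohort(small_cfg)
    X, truth = simulate_expression(small_cfg, annotation)
    return annotation, X, truth


@pytest.fixture(scope="session")
def table_cfg() -> SimulationConfig:
    """Full-design cohort mirroring the emulated study (43 of 48 arrays used)."""
    return SimulationConfig(seed=5)


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg computed from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
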