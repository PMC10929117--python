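import numpy as np
import pandas as pd
import pytest

import sistermem as sm


@pytest.fixture
def gen1_config():
    """Default generation-1 study: 30 sister pairs, 10% memory genes."""
    return sm.SimulationConfig(
        n_families=30, generation=1, n_genes=300, seed=0,
        conditions=("self_renewing",),
    )


@pytest.fixture
def gen2_config():
    return sm.SimulationConfig(
        n_families=8, generation=2, n_genes=100, seed=0,
        conditions=("self_renewing",),
    )


@pytest.fixture
def gen1_memory_data(gen1_config):
    """Pedigree + expression with planted memory genes (ICC 0.6)."""
    ped = sm.simulate_pedigree(gen1_config)
    adata = sm.simulate_expression(ped, gen1_config)
    return ped, adata


def make_paired_gaussian(q, icc, rng, condition=None, beta=0.0):
    """Independent oracle generator: q pairs with known ICC, by hand."""
    pair_ids = np.repeat([f"p{i}" for i in range(q)], 2)
    b = np.repeat(rng.normal(0.0, np.sqrt(icc), q), 2)
    y = b + rng.normal(0.0, np.sqrt(1.0 - icc), 2 * q)
    if condition is not None:
        y = y + beta * (np.asarray(condition) == "differentiating")
    return y, pair_ids


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
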