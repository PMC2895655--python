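"""Shared fixtures: small simulated studies built once per session."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coregmap import SimulationConfig, simulate_all

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from coregmap.chip import ChipReplicateMatrix


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast configuration exercising every stage."""
    return SimulationConfig(
        genome_length=300_000,
        n_genes=150,
        n_bound_A=10,
        n_bound_B=10,
        n_offtarget_per_antibody=3,
        n_enhancers=9,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def toy_chip_matrix() -> ChipReplicateMatrix:
    """3 fragments x 2 IP replicates with hand-checkable ranks."""
    data = pd.DataFrame(
        {
            "ab1_ip_T1_r1": [1.0, 0.26, -0.32],
            "ab1_ip_T1_r2": [0.85, -0.15, 0.14],
        },
        index=pd.Index(["f1", "f2", "f3"], name="fragment"),
    )
    return ChipReplicateMatrix(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
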