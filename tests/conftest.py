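"""Shared fixtures: the default synthetic run is generated once per session."""

import numpy as np
import pytest

from enhdyn.synthetic import (
    SimConfig,
    generate_truth,
    simulate_counts,
    simulate_expression,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale config for plumbing tests that do not need stable statistics."""
    return SimConfig(
        seed=3,
        n_chroms=1,
        chrom_length=1_000_000,
        n_enhancers=150,
        n_genes=80,
    )


@pytest.fixture(scope="session")
def sim(default_config):
    truth, genes = generate_truth(default_config)
    return {"truth": truth, "genes": genes, "config": default_config}


@pytest.fixture(scope="session")
def sim_tracks(sim):
    return simulate_tracks(sim["truth"], sim["config"])


@pytest.fixture(scope="session")
def counts_k4(sim):
    return simulate_counts(sim["truth"], sim["config"], "H3K4me1")


@pytest.fixture(scope="session")
def counts_k27(sim):
    return simulate_counts(sim["truth"], sim["config"], "H3K27ac")


@pytest.fixture(scope="session")
def expression(sim):
    return simulate_expression(sim["truth"], sim["genes"], sim["config"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
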