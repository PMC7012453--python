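"""Shared fixtures: small simulations for unit tests and the default-scale
study conditions (built once per session) for the acceptance properties."""
import logging

import numpy as np
import pytest

from funcgroups.encoding import run_model_suite
from funcgroups.network import build_functional_graph
from funcgroups.simulate import (
    default_synthetic_dataset,
    generate_coupling,
    generate_protocol,
    generate_tuning,
    simulate_population,
)

# benign per-neuron warnings (zero-weight columns etc.) drown test output
logging.getLogger("funcgroups").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sim():
    """20 neurons, 6 short blocks: fast end-to-end exercises."""
    protocol = generate_protocol(n_blocks=6, presentation_frames=15, grey_frames=8, seed=1)
    coupling = generate_coupling(20, edge_density=0.15, seed=2)
    tuning = generate_tuning(20, seed=3)
    return simulate_population(protocol, coupling, tuning, seed=4)


@pytest.fixture(scope="session")
def small_ds(small_sim):
    return small_sim.dataset


@pytest.fixture(scope="session")
def small_graph(small_ds):
    return build_functional_graph(small_ds, max_lag=8)


@pytest.fixture(scope="session")
def small_comparison(small_ds, small_graph):
    return run_model_suite(small_ds, small_graph, variants=("unrestricted",))


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 100 neurons, 10 blocks, ~9,000 frames,
    planted mostly-positive strong lag-0/1 coupling, no running modulation."""
    return default_synthetic_dataset(seed=1)


@pytest.fixture(scope="session")
def default_graph(default_sim):
    return build_functional_graph(default_sim.dataset)


@pytest.fixture(scope="session")
def default_comparison(default_sim, default_graph):
    return run_model_suite(default_sim.dataset, default_graph)


@pytest.fixture(scope="session")
def run_modulated_sim():
    """Default scale plus running-driven global gain: the shared-variability
    regime for the coupled-vs-uncoupled decoding comparison."""
    return default_synthetic_dataset(seed=1, run_gain=0.3)


@pytest.fixture(scope="session")
def null_sim():
    """No coupling, no tuning: pure private noise (null for the graph)."""
    protocol = generate_protocol(n_blocks=6, seed=11)
    coupling = generate_coupling(30, edge_density=1e-9, seed=12)
    coupling.weight[:] = 0.0
    tuning = generate_tuning(30, tuned_fraction=0.0, seed=13)
    return simulate_population(protocol, coupling, tuning, seed=14)
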