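"""Shared fixtures: toy networks, a random-instance generator, and the
scaled planted-subgraph benchmark run reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from deregsub import (
    SubgraphInstance,
    DirectedNetwork,
    SimulationConfig,
    SolverSettings,
    generate_network,
    run_benchmark,
)


@pytest.fixture
def triangle() -> DirectedNetwork:
    """A -> B -> C with shortcut A -> C."""
    return DirectedNetwork("ABC", [("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def triangle_instance(triangle) -> SubgraphInstance:
    return SubgraphInstance(
        network=triangle,
        score={"A": 1.0, "B": 0.0, "C": 1.0},
        receptors=frozenset("A"),
        terminals=frozenset("C"),
        k_min=2,
        k_max=3,
    )


def random_digraph(rng: np.random.Generator, n: int, p_edge: float = 0.25) -> DirectedNetwork:
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p_edge
    ]
    return DirectedNetwork(nodes, edges)


def random_instance(
    rng: np.random.Generator,
    sense: str = "maximize",
    absolute: bool = False,
    binary_scores: bool = False,
) -> SubgraphInstance:
    """Random small instance: 8-12 nodes, k in [2,5], random receptor and
    terminal sets of size 0-3, uniform (or Bernoulli) node scores."""
    n = int(rng.integers(8, 13))
    net = random_digraph(rng, n)
    nodes = list(net.nodes)
    if binary_scores:
        score = {v: float(rng.integers(0, 2)) for v in nodes}
    else:
        score = {v: float(rng.uniform(-1.0, 1.0)) for v in nodes}
    r_size = int(rng.integers(0, 4))
    t_size = int(rng.integers(0, 4))
    receptors = frozenset(rng.choice(nodes, size=r_size, replace=False)) if r_size else frozenset()
    terminals = frozenset(rng.choice(nodes, size=t_size, replace=False)) if t_size else frozenset()
    return SubgraphInstance(
        network=net,
        score=score,
        receptors=receptors,
        terminals=terminals,
        k_min=2,
        k_max=5,
        sense=sense,
        absolute=absolute,
    )


BENCHMARK_CONFIG = SimulationConfig(
    p=0.01,
    p_prime=0.99,
    true_size_min=8,
    true_size_max=12,
    k_min=6,
    k_max=15,
    n_instances=20,
    time_limit=600.0,
    seed=1,
)


@pytest.fixture(scope="session")
def benchmark_network() -> DirectedNetwork:
    return generate_network(300, seed=BENCHMARK_CONFIG.seed)


@pytest.fixture(scope="session")
def benchmark_table(benchmark_network):
    """Planted-subgraph recovery benchmark at the scaled study conditions."""
    return run_benchmark(
        benchmark_network,
        BENCHMARK_CONFIG,
        SolverSettings(time_limit=BENCHMARK_CONFIG.time_limit),
    )
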