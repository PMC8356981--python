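"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sbncomm import ConnectomeMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sbncomm.detection import criterion_value


def set_partitions(n: int):
    """All set partitions of n items as 0-based label lists (Bell(n) many)."""
    if n == 1:
        yield [0]
        return
    for p in set_partitions(n - 1):
        for c in range(max(p) + 2):
            yield p + [c]


def exhaustive_best_value(W: np.ndarray, criterion: str = "newman", scale=None) -> float:
    """Brute-force optimum of a quality criterion over all set partitions."""
    best = -np.inf
    for p in set_partitions(W.shape[0]):
        v = criterion_value(W, np.asarray(p) + 1, criterion, scale)
        best = max(best, v)
    return best


def two_cliques(k: int, bridge: float = 0.01) -> np.ndarray:
    """Two k-cliques (unit weights) joined by one bridge edge."""
    n = 2 * k
    W = np.zeros((n, n))
    for i in range(k):
        for j in range(i + 1, k):
            W[i, j] = W[j, i] = 1.0
            W[i + k, j + k] = W[j + k, i + k] = 1.0
    W[0, k] = W[k, 0] = bridge
    return W


def random_connected(n: int, p: float, rng: np.random.Generator,
                     low: float = 0.5, high: float = 1.0) -> ConnectomeMatrix:
    """Rejection-sample a connected weighted Erdos-Renyi graph."""
    while True:
        W = np.triu((rng.random((n, n)) < p) * rng.uniform(low, high, (n, n)), 1)
        cm = ConnectomeMatrix(W + W.T)
        if cm.is_connected():
            return cm


@pytest.fixture(scope="session")
def small_fixture_graphs() -> list[np.ndarray]:
    """Connected graphs on <= 8 nodes spanning easy and adversarial shapes:
    clique pairs, a path, a cycle, a star and random weighted graphs."""
    graphs = [two_cliques(3), two_cliques(4)]
    path = np.zeros((6, 6))
    for i in range(5):
        path[i, i + 1] = path[i + 1, i] = 1.0
    graphs.append(path)
    cycle = path.copy()
    cycle[0, 5] = cycle[5, 0] = 1.0
    graphs.append(cycle)
    star = np.zeros((7, 7))
    star[0, 1:] = star[1:, 0] = 1.0
    graphs.append(star)
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        g = random_connected(8, 0.45, rng, low=0.2, high=1.0)
        graphs.append(g.weights)
    return graphs


@pytest.fixture(scope="session")
def planted_graph():
    """The default desk-scale planted-partition fixture: 4 modules x 10 nodes."""
    from sbncomm import generate_planted_partition_graph

    return generate_planted_partition_graph(40, [10] * 4, 0.8, 0.05, seed=7)
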