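"""Shared fixtures: the worked 4-node toy network and random-graph helpers."""

from __future__ import annotations

import numpy as np
import pytest

from treeify import WeightedNetwork, all_pairs_similarity, build_tree
from treeify.path_strength import PathStrengthParams


TOY_EDGES = [("A", "B", 0.8), ("A", "C", 0.6), ("B", "C", 0.4), ("C", "D", 0.5)]


@pytest.fixture
def toy_net() -> WeightedNetwork:
    """4-node network whose similarities/tree/hubs are known by hand."""
    return WeightedNetwork(TOY_EDGES)


@pytest.fixture
def params() -> PathStrengthParams:
    return PathStrengthParams()


@pytest.fixture
def toy_store(toy_net, params):
    return all_pairs_similarity(toy_net, params)


@pytest.fixture
def toy_tree(toy_net, toy_store):
    return build_tree(toy_net, toy_store)


def random_weighted_net(
    seed: int, n_lo: int = 4, n_hi: int = 10, p: float = 0.45
) -> WeightedNetwork:
    """Seeded Erdos-Renyi topology with uniform(0.05, 1) weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    names = [f"v{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j], float(rng.uniform(0.05, 1.0))))
    return WeightedNetwork(edges, nodes=names)
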