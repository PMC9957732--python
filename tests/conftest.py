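"""Shared fixtures: small synthetic configurations and additive-tree oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from potspread import DistanceMatrix, SimConfig, simulate_sites


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Cheap study-shaped configuration for unit tests (fewer sites/traits)."""
    return SimConfig(
        n_sites=12,
        traits_per_block={"decoration": 12, "morphology": 12, "technology": 8, "use": 6},
        n_posterior_draws=100,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sites(small_config):
    sites, truth = simulate_sites(small_config)
    return sites, truth


# ---------------------------------------------------------------------------
# additive (tree-metric) oracles for the splits-network tests
# ---------------------------------------------------------------------------


def tree_metric(taxa: list[str], splits_weights: dict[frozenset, float]) -> DistanceMatrix:
    """Distance matrix of a weighted split system: d(i,j) = sum of separating weights."""
    n = len(taxa)
    d = np.zeros((n, n))
    for s, w in splits_weights.items():
        for i, j in itertools.combinations(range(n), 2):
            if (taxa[i] in s) != (taxa[j] in s):
                d[i, j] += w
                d[j, i] += w
    return DistanceMatrix(taxa, d, "tree")


def all_binary_trees_5(taxa: list[str]) -> list[dict[frozenset, float]]:
    """All 15 unrooted binary tree topologies on 5 taxa as split sets.

    Each tree = 5 trivial splits + 2 internal splits given by a disjoint pair
    of 2-subsets; weights are filled in by the caller.
    """
    assert len(taxa) == 5
    trees = []
    pairs = list(itertools.combinations(taxa, 2))
    for a, b in itertools.combinations(pairs, 2):
        if set(a) & set(b):
            continue
        splits = [frozenset([t]) for t in taxa] + [frozenset(a), frozenset(b)]
        trees.append(splits)
    assert len(trees) == 15
    return trees
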