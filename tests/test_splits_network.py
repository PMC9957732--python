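"""NeighborNet ordering, NNLS split weights and NEXUS interchange."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import all_binary_trees_5, tree_metric
from potspread import (
    DistanceMatrix,
    neighbor_net,
    neighbornet_ordering,
    read_splits_nexus,
    split_weights,
    write_splits_nexus,
)
from potspread.splits_network import circular_splits


def circular_pairs(order: list[str]) -> set[frozenset]:
    return {frozenset((order[i], order[(i + 1) % len(order)])) for i in range(len(order))}


class TestOrdering:
    def test_quartet_tree_places_cherries_adjacent(self):
        # tree ((A,B),(C,D)) with internal branch 3
        d = tree_metric(
            ["A", "B", "C", "D"],
            {frozenset(["A"]): 1.0, frozenset(["B"]): 2.0, frozenset(["C"]): 1.5,
             frozenset(["D"]): 1.0, frozenset(["A", "B"]): 3.0},
        )
        order = neighbornet_ordering(d)
        adj = circular_pairs(order)
        assert frozenset(("A", "B")) in adj and frozenset(("C", "D")) in adj

    def test_identical_taxa_adjacent(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6))
        a = a + a.T
        np.fill_diagonal(a, 0)
        a[4, :] = a[5, :]
        a[:, 4] = a[:, 5]
        a[4, 5] = a[5, 4] = 0.0
        a[4, 4] = 0.0
        d = DistanceMatrix([f"t{i}" for i in range(6)], a)
        order = neighbornet_ordering(d)
        assert frozenset(("t4", "t5")) in circular_pairs(order)

    def test_ordering_equivariant_under_label_permutation(self):
        rng = np.random.default_rng(1)
        a = rng.random((7, 7))
        a = a + a.T
        np.fill_diagonal(a, 0)
        d = DistanceMatrix([f"t{i}" for i in range(7)], a)
        base = neighbornet_ordering(d)
        perm = rng.permutation(7)
        labels = [d.labels[i] for i in perm]
        other = neighbornet_ordering(d.align_to(labels))
        # compare as circular sequences up to rotation and reflection
        def canon(order):
            best = None
            for o in (order, order[::-1]):
                for k in range(len(o)):
                    cand = tuple(o[k:] + o[:k])
                    best = cand if best is None or cand < best else best
            return best
        assert canon(base) == canon(other)

    def test_too_few_taxa_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], 1 - np.eye(3))
        with pytest.raises(ValueError, match="4 taxa"):
            neighbornet_ordering(d)


class TestSplitWeights:
    def test_three_taxon_closed_form(self):
        v = np.array([[0, 3.0, 5.0], [3.0, 0, 4.0], [5.0, 4.0, 0]])
        d = DistanceMatrix(["A", "B", "C"], v)
        net = split_weights(d, ["A", "B", "C"])
        w = {s: w for s, w in zip(net.splits, net.weights)}
        assert w[frozenset(["B"])] == pytest.approx((3 + 4 - 5) / 2)
        assert w[frozenset(["C"])] == pytest.approx((5 + 4 - 3) / 2)
        assert w[frozenset(["B", "C"])] == pytest.approx((3 + 5 - 4) / 2)
        assert net.fit < 1e-10

    def test_quartet_tree_recovers_branch_lengths(self):
        lengths = {frozenset(["A"]): 1.0, frozenset(["B"]): 2.0, frozenset(["C"]): 1.5,
                   frozenset(["D"]): 0.7, frozenset(["A", "B"]): 3.0}
        d = tree_metric(["A", "B", "C", "D"], lengths)
        net = neighbor_net(d)
        assert net.fit < 1e-8
        got = {s: w for s, w in zip(net.splits, net.weights)}
        for s, w in lengths.items():
            match = [gw for gs, gw in got.items() if gs == s or gs == frozenset(d.labels) - s]
            assert match and match[0] == pytest.approx(w, abs=1e-8)
        assert len(got) == len(lengths)

    def test_all_zero_distances_give_no_splits(self):
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        net = neighbor_net(d)
        assert len(net.splits) == 0

    def test_nnls_matches_brute_force_qp_on_quartets(self):
        """Exhaustive active-set search (all 2^6 support sets, feasible
        least squares) equals the NNLS solution on random 4-taxon metrics."""
        rng = np.random.default_rng(2)
        order = list("abcd")
        splits = circular_splits(order)
        iu = np.triu_indices(4, 1)
        pos = {t: i for i, t in enumerate(order)}
        A = np.zeros((6, len(splits)))
        for k, s in enumerate(splits):
            for r, (i, j) in enumerate(zip(*iu)):
                A[r, k] = (order[i] in s) != (order[j] in s)
        for _ in range(10):
            m = rng.random((4, 4))
            m = m + m.T
            np.fill_diagonal(m, 0)
            d = DistanceMatrix(order, m)
            net = split_weights(d, order, weight_threshold=-1.0)
            dvec = d.values[iu]
            best = None
            for active in itertools.product([0, 1], repeat=len(splits)):
                idx = [k for k, a in enumerate(active) if a]
                w = np.zeros(len(splits))
                if idx:
                    sol, *_ = np.linalg.lstsq(A[:, idx], dvec, rcond=None)
                    if (sol < -1e-9).any():
                        continue
                    w[idx] = sol
                resid = np.linalg.norm(A @ w - dvec)
                if best is None or resid < best - 1e-12:
                    best = resid
            assert net.fit == pytest.approx(best, abs=1e-8)

    def test_residuals_unbiased_on_random_metrics(self):
        rng = np.random.default_rng(3)
        means = []
        for _ in range(10):
            m = rng.random((7, 7))
            m = m + m.T
            np.fill_diagonal(m, 0)
            net = neighbor_net(DistanceMatrix([f"t{i}" for i in range(7)], m))
            order = net.taxa
            iu = np.triu_indices(7, 1)
            d = DistanceMatrix([f"t{i}" for i in range(7)], m).align_to(order).values[iu]
            pos = {t: i for i, t in enumerate(order)}
            fitted = np.zeros_like(d)
            for s, w in zip(net.splits, net.weights):
                for r, (i, j) in enumerate(zip(*iu)):
                    if (order[i] in s) != (order[j] in s):
                        fitted[r] += w
            means.append(np.mean(fitted - d))
        assert abs(np.mean(means)) < 0.02

    def test_five_taxon_trees_exact(self):
        """All 15 unrooted binary topologies on 5 taxa, random branch lengths:
        split set and weights recovered exactly."""
        taxa = list("abcde")
        rng = np.random.default_rng(4)
        for splits in all_binary_trees_5(taxa):
            weights = {s: float(rng.uniform(0.5, 3.0)) for s in splits}
            d = tree_metric(taxa, weights)
            net = neighbor_net(d)
            assert net.fit < 1e-8
            got = {}
            full = frozenset(taxa)
            for s, w in zip(net.splits, net.weights):
                key = min(s, full - s, key=lambda x: (len(x), sorted(x)))
                got[key] = w
            expect = {min(s, full - s, key=lambda x: (len(x), sorted(x))): w
                      for s, w in weights.items()}
            assert set(got) == set(expect)
            for k in expect:
                assert got[k] == pytest.approx(expect[k], abs=1e-8)


class TestNexus:
    def test_round_trip_preserves_cycle_and_weights(self, tmp_path):
        d = tree_metric(
            ["A", "B", "C D", "E'x"],
            {frozenset(["A"]): 1.0, frozenset(["B"]): 2.0, frozenset(["C D"]): 1.5,
             frozenset(["E'x"]): 0.7, frozenset(["A", "B"]): 3.0},
        )
        net = neighbor_net(d)
        path = tmp_path / "splits.nex"
        write_splits_nexus(net, path)
        back = read_splits_nexus(path)
        assert back.taxa == net.taxa  # quoted labels with spaces survive
        assert len(back.splits) == len(net.splits)
        ours = dict(zip(net.splits, net.weights))
        for s, w in zip(back.splits, back.weights):
            key = s if s in ours else frozenset(net.taxa) - s
            assert w == pytest.approx(ours[key], abs=1e-10)

    def test_empty_network_rejected(self, tmp_path):
        from potspread.splits_network import SplitsNetwork

        with pytest.raises(ValueError, match="empty"):
            write_splits_nexus(SplitsNetwork([], [], np.empty(0), 0.0), tmp_path / "x.nex")
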