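"""NeighborNet circular split systems from dissimilarity matrices.

NeighborNet generalizes neighbour joining: instead of forcing the data onto
a tree it produces a *circular split system* — an ordering of the taxa
around a circle plus weighted splits, each split realizable as a contiguous
arc of the ordering.  Conflicting (reticulate) signal shows up as
overlapping splits; a perfectly tree-like (additive) input recovers exactly
the tree's splits with the branch lengths as weights.

Two stages:

1. **Agglomerative ordering** — repeatedly select a pair of clusters by the
   neighbour-joining adjusted distance Q, pick the closest pair of member
   nodes by the same criterion, and merge, replacing any three consecutive
   path nodes ``a, b, c`` by two new nodes ``u, v`` with

       d(u, z) = 2/3 d(a, z) + 1/3 d(b, z)
       d(v, z) = 1/3 d(b, z) + 2/3 d(c, z)
       d(u, v) = (d(a, b) + d(a, c) + d(b, c)) / 3

   until three or fewer nodes remain; expanding the reductions in reverse
   yields the circular ordering.

2. **Split weighting** — nonnegative least squares fit of the n(n−1)/2
   circular-interval split indicators to the observed distances.

Ties in the agglomeration are broken toward the lowest-index pair so output
is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .io_core import DistanceMatrix

#: splits with fitted weight below this are numerical dust and dropped
WEIGHT_THRESHOLD = 1e-9


@dataclass
class SplitsNetwork:
    """Circular taxon ordering with weighted interval splits."""

    taxa: list[str]                       # circular ordering
    splits: list[frozenset[str]]          # the side not containing taxa[0]
    weights: np.ndarray
    fit: float                            # ||A w − d|| residual norm
    converged: bool = True

    def split_table(self) -> list[tuple[float, tuple[str, ...]]]:
        order = {t: i for i, t in enumerate(self.taxa)}
        return [
            (float(w), tuple(sorted(s, key=order.get)))
            for w, s in sorted(zip(self.weights, self.splits), reverse=True, key=lambda t: t[0])
        ]


# ---------------------------------------------------------------------------
# Stage 1: agglomerative circular ordering
# ---------------------------------------------------------------------------


class _NetState:
    """Growable distance store over active/retired node ids."""

    def __init__(self, d: np.ndarray):
        n = d.shape[0]
        cap = 3 * n + 8  # each reduction adds 2 nodes, there are < n reductions
        self.D = np.zeros((cap, cap))
        self.D[:n, :n] = d
        self.next_id = n

    def new_node(self) -> int:
        i = self.next_id
        self.next_id += 1
        if i >= self.D.shape[0]:
            grown = np.zeros((2 * self.D.shape[0],) * 2)
            grown[: self.D.shape[0], : self.D.shape[0]] = self.D
            self.D = grown
        return i

    def d(self, a: int, b: int) -> float:
        return self.D[a, b]


def _cluster_dist(state: _NetState, c1: Sequence[int], c2: Sequence[int]) -> float:
    return float(np.mean([[state.d(a, b) for b in c2] for a in c1]))


def _select_clusters(state: _NetState, clusters: list[list[int]]) -> tuple[int, int]:
    m = len(clusters)
    Dc = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            Dc[i, j] = Dc[j, i] = _cluster_dist(state, clusters[i], clusters[j])
    R = Dc.sum(axis=1)
    best, best_q = None, np.inf
    for i in range(m):
        for j in range(i + 1, m):
            q = (m - 2) * Dc[i, j] - R[i] - R[j]
            if q < best_q - 1e-12:
                best_q, best = q, (i, j)
    return best


def _select_nodes(
    state: _NetState, clusters: list[list[int]], i: int, j: int
) -> tuple[int, int]:
    """Pick (x in cluster i, y in cluster j) by the NJ criterion over the
    element set {nodes of the two clusters} ∪ {other clusters as units}."""
    c1, c2 = clusters[i], clusters[j]
    if len(c1) == 1 and len(c2) == 1:
        return c1[0], c2[0]
    others = [clusters[k] for k in range(len(clusters)) if k not in (i, j)]
    elements: list[list[int]] = [[x] for x in c1 + c2] + others
    m_hat = len(elements)
    R = {}
    for x in c1 + c2:
        R[x] = sum(_cluster_dist(state, [x], e) for e in elements if e != [x])
    best, best_q = None, np.inf
    for x in c1:
        for y in c2:
            q = (m_hat - 2) * state.d(x, y) - R[x] - R[y]
            if q < best_q - 1e-12:
                best_q, best = q, (x, y)
    return best


def _reduce_path(
    state: _NetState, path: list[int], expansions: list[tuple[int, int, tuple[int, int, int]]]
) -> list[int]:
    """Collapse a 3- or 4-node path to 2 nodes via successive reductions."""
    while len(path) > 2:
        a, b, c = path[0], path[1], path[2]
        u, v = state.new_node(), state.new_node()
        for z in range(state.next_id - 2):
            state.D[u, z] = state.D[z, u] = (2 * state.d(a, z) + state.d(b, z)) / 3
            state.D[v, z] = state.D[z, v] = (state.d(b, z) + 2 * state.d(c, z)) / 3
        duv = (state.d(a, b) + state.d(a, c) + state.d(b, c)) / 3
        state.D[u, v] = state.D[v, u] = duv
        expansions.append((u, v, (a, b, c)))
        path = [u, v] + path[3:]
    return path


def neighbornet_ordering(dm: DistanceMatrix) -> list[str]:
    """Circular taxon ordering by the NeighborNet agglomeration.

    For additive (tree-like) inputs the ordering is compatible with the
    underlying tree; identical taxa end up adjacent.  Output is a circular
    permutation of ``dm.labels`` — rotations/reflections are equivalent.
    """
    n = dm.n
    if n < 4:
        raise ValueError("NeighborNet ordering needs at least 4 taxa")
    state = _NetState(dm.values)
    clusters: list[list[int]] = [[i] for i in range(n)]
    expansions: list[tuple[int, int, tuple[int, int, int]]] = []

    def total_nodes() -> int:
        return sum(len(c) for c in clusters)

    while len(clusters) > 1 and total_nodes() > 3:
        i, j = _select_clusters(state, clusters)
        x, y = _select_nodes(state, clusters, i, j)
        c1 = list(clusters[i]) if clusters[i][-1] == x else list(reversed(clusters[i]))
        c2 = list(clusters[j]) if clusters[j][0] == y else list(reversed(clusters[j]))
        path = _reduce_path(state, c1 + c2, expansions)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [path]

    order: list[int] = [node for c in clusters for node in c]
    while expansions:
        u, v, (a, b, c) = expansions.pop()
        pu = order.index(u)
        pv = order.index(v)
        if (pu + 1) % len(order) == pv:
            replacement, at = [a, b, c], pu
        elif (pv + 1) % len(order) == pu:
            replacement, at = [c, b, a], pv
        else:  # pragma: no cover - reductions always keep u,v adjacent
            raise AssertionError("reduction pair separated in ordering")
        if at == len(order) - 1:  # wraps around the circle
            order = replacement[1:] + order[1:at] + [replacement[0]]
        else:
            order = order[:at] + replacement + order[at + 2:]
    assert sorted(order) == list(range(n))
    return [dm.labels[i] for i in order]


# ---------------------------------------------------------------------------
# Stage 2: nonnegative least-squares split weights
# ---------------------------------------------------------------------------


def circular_splits(ordering: Sequence[str]) -> list[frozenset[str]]:
    """All n(n−1)/2 interval splits of a circular ordering.

    Each split is represented by its side not containing ``ordering[0]``.
    """
    n = len(ordering)
    out = []
    for a in range(1, n):
        for b in range(a, n):
            out.append(frozenset(ordering[a: b + 1]))
    return out


def split_weights(
    dm: DistanceMatrix,
    ordering: Sequence[str],
    weight_threshold: float = WEIGHT_THRESHOLD,
) -> SplitsNetwork:
    """Fit nonnegative split weights to the distances over interval splits.

    Solves ``min ‖d − Σ_s w_s δ_s‖²`` subject to ``w ≥ 0`` with an
    active-set NNLS solver; splits below ``weight_threshold`` are dropped.
    """
    if sorted(ordering) != sorted(dm.labels):
        raise ValueError("ordering must cover exactly the matrix labels")
    dm = dm.align_to(list(ordering))
    n = dm.n
    splits = circular_splits(ordering)
    iu = np.triu_indices(n, k=1)
    d = dm.values[iu]
    pos = np.arange(n)
    A = np.zeros((d.size, len(splits)))
    for s_idx, (a, b) in enumerate(
        (a, b) for a in range(1, n) for b in range(a, n)
    ):
        inside = (pos >= a) & (pos <= b)
        sep = inside[iu[0]] ^ inside[iu[1]]
        A[:, s_idx] = sep
    try:
        w, rnorm = nnls(A, d, maxiter=max(30 * len(splits), 3000))
        converged = True
    except RuntimeError:
        w, rnorm = nnls(A, d, maxiter=10 * 30 * len(splits))
        converged = False
    keep = w > weight_threshold
    return SplitsNetwork(
        taxa=list(ordering),
        splits=[s for s, k in zip(splits, keep) if k],
        weights=w[keep],
        fit=float(rnorm),
        converged=converged,
    )


def neighbor_net(dm: DistanceMatrix, weight_threshold: float = WEIGHT_THRESHOLD) -> SplitsNetwork:
    """Full NeighborNet: ordering then nonnegative split weights."""
    return split_weights(dm, neighbornet_ordering(dm), weight_threshold)


# ---------------------------------------------------------------------------
# NEXUS SPLITS interchange
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    if re.search(r"[\s'();,\[\]]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_splits_nexus(net: SplitsNetwork, path: str | Path) -> None:
    """Write a NEXUS file with TAXA and SPLITS blocks (SplitsTree-compatible)."""
    if not net.taxa:
        raise ValueError("empty network")
    index = {t: i + 1 for i, t in enumerate(net.taxa)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(net.taxa)};\n")
        fh.write("TAXLABELS\n")
        for t in net.taxa:
            fh.write(f"  {_quote(t)}\n")
        fh.write(";\nEND;\n\nBEGIN SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={len(net.taxa)} NSPLITS={len(net.splits)};\n")
        fh.write("FORMAT LABELS=NO WEIGHTS=YES;\n")
        fh.write("CYCLE " + " ".join(str(index[t]) for t in net.taxa) + ";\n")
        fh.write("MATRIX\n")
        for k, (s, w) in enumerate(zip(net.splits, net.weights), start=1):
            members = " ".join(str(index[t]) for t in sorted(s, key=index.get))
            fh.write(f"[{k}] {w:.12g} {members},\n")
        fh.write(";\nEND;\n")


def read_splits_nexus(path: str | Path) -> SplitsNetwork:
    """Read back a NEXUS SPLITS file written by :func:`write_splits_nexus`."""
    text = Path(path).read_text()
    taxa_m = re.search(r"TAXLABELS\s+(.*?);", text, re.S | re.I)
    if not taxa_m:
        raise ValueError(f"{path}: no TAXLABELS block")
    taxa = [
        t[1:-1].replace("''", "'") if t.startswith("'") else t
        for t in re.findall(r"'(?:[^']|'')*'|\S+", taxa_m.group(1))
    ]
    cycle_m = re.search(r"CYCLE\s+([\d\s]+);", text, re.I)
    order = [taxa[int(i) - 1] for i in cycle_m.group(1).split()] if cycle_m else taxa
    matrix_m = re.search(r"MATRIX\s*(.*?);\s*END", text, re.S | re.I)
    if not matrix_m:
        raise ValueError(f"{path}: no SPLITS MATRIX block")
    splits, weights = [], []
    for line in matrix_m.group(1).strip().splitlines():
        line = re.sub(r"\[\d+\]", "", line).strip().rstrip(",")
        if not line:
            continue
        parts = line.split()
        weights.append(float(parts[0]))
        splits.append(frozenset(taxa[int(i) - 1] for i in parts[1:]))
    return SplitsNetwork(order, splits, np.asarray(weights), fit=np.nan)
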