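"""Per-timepoint minimum spanning trees from dynamic connectivity.

Each time point's correlation matrix is converted to edge weights (the
reciprocal of connection strength, i.e. the cost of information exchange)
and the minimum spanning tree is extracted with Kruskal's algorithm:
edges are ranked from lowest to highest weight and added unless they close
a cycle, until all nodes are connected; the result is binarized.

Weight modes: ``abs_reciprocal`` (default) ranks by 1/|c|, so the tree
collects the strongest connections regardless of sign; ``signed_reciprocal``
is the literal 1/c, kept for exact-literal replication (it ranks strong
negative correlations first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dcc import DynamicConnectivity

logger = logging.getLogger(__name__)

WEIGHT_CAP = 1e12
WeightMode = Literal["abs_reciprocal", "signed_reciprocal"]


@dataclass
class WeightMatrix:
    w: np.ndarray
    mode: WeightMode = "abs_reciprocal"

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class SpanningTree:
    """Binarized spanning tree: n nodes, exactly n-1 edges, connected, acyclic."""

    n: int
    edges: frozenset[tuple[int, int]]  # 0-based, i < j

    def __post_init__(self) -> None:
        if len(self.edges) != self.n - 1:
            raise ValueError(f"a spanning tree on {self.n} nodes needs {self.n - 1} edges")

    @property
    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n, self.n), dtype=np.int8)
        for i, j in self.edges:
            adj[i, j] = 1
            adj[j, i] = 1
        return adj

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class TreeSeries:
    trees: list[SpanningTree]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.trees and len({t.n for t in self.trees}) != 1:
            raise ValueError("all trees in a series must share the node count")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return self.trees[0].n


def weights_from_connectivity(
    c_slice: np.ndarray, mode: WeightMode = "abs_reciprocal"
) -> WeightMatrix:
    """Reciprocal-of-connectivity edge weights; near-zero entries capped."""
    c = np.asarray(c_slice, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("connectivity slice must be a square matrix")
    base = np.abs(c) if mode == "abs_reciprocal" else c
    near_zero = np.abs(c) < 1e-12
    with np.errstate(divide="ignore"):
        w = np.where(near_zero, WEIGHT_CAP, 1.0 / np.where(near_zero, 1.0, base))
    n_capped = int(near_zero.sum() - near_zero.trace())
    if n_capped:
        logger.warning("weights_from_connectivity: %d near-zero entries capped at %g",
                       n_capped, WEIGHT_CAP)
    return WeightMatrix(w=w, mode=mode)


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def kruskal_mst(weights: WeightMatrix | np.ndarray) -> SpanningTree:
    """Kruskal's algorithm with deterministic (weight, i, j) tie-breaking."""
    w = weights.w if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite edge weights")
    order = np.lexsort((ju, iu, vals))  # sort by weight, then i, then j
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("weight matrix does not admit a spanning tree")
    return SpanningTree(n=n, edges=frozenset(edges))


def tree_series(
    conn: DynamicConnectivity, mode: WeightMode = "abs_reciprocal"
) -> TreeSeries:
    """One minimum spanning tree per time point of the connectivity tensor."""
    trees = []
    for t in range(conn.t_len):
        try:
            trees.append(kruskal_mst(weights_from_connectivity(conn.tensor[:, :, t], mode)))
        except ValueError as exc:
            raise ValueError(f"subject {conn.subject_id!r}, time point {t}: {exc}") from exc
    return TreeSeries(trees=trees, subject_id=conn.subject_id)
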