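"""Maximum-weight spanning tree of a connectivity matrix and its metrics.

The tree is the backbone of the n-1 strongest links, built with Kruskal's
algorithm on descending weights (equivalently, the minimum spanning tree of
lengths 1/W).  Topology metrics treat the tree as unweighted: path lengths
count edges.  With M = N - 1 edges:

* max degree  K_max = max_i deg(i) / M
* leaf fraction  Lf = (#degree-1 nodes) / M
* diameter  D = (longest path, in edges) / M
* eccentricity  ECC = mean_i ecc(i) / M
* betweenness  BC = max_i bc(i) / ((N-1)(N-2)/2)
* tree hierarchy  Th = Lf / (2 BC), balancing short diameter against
  central overload.

Negative connectivity values are valid (weak) candidate edges and rank below
all positive ones; exact zeros mean "no edge".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = ["SpanningTree", "MSTMetricsRecord", "extract_mst", "mst_metrics"]


@dataclass
class SpanningTree:
    """An N-node spanning tree as an edge list of (i, j, weight)."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def to_csv(self, path) -> None:
        labels = self.node_labels or tuple(str(i) for i in range(self.n_nodes))
        pd.DataFrame(
            [(labels[i], labels[j], w) for i, j, w in self.edges],
            columns=["i_label", "j_label", "weight"],
        ).to_csv(path, index=False)


@dataclass
class MSTMetricsRecord:
    """The six normalised tree metrics (all in [0, 1])."""

    k_max: float
    bc: float
    ecc: float
    diameter: float
    leaf_fraction: float
    tree_hierarchy: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mst_k_max": self.k_max,
            "mst_bc": self.bc,
            "mst_ecc": self.ecc,
            "mst_diameter": self.diameter,
            "mst_leaf_fraction": self.leaf_fraction,
            "mst_tree_hierarchy": self.tree_hierarchy,
        }


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

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


def extract_mst(W: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Maximum-weight spanning tree by Kruskal's algorithm with union-find.

    Candidate edges are all nonzero off-diagonal entries, scanned in
    descending weight; ties broken by (i, j) lexicographic order.  A
    disconnected input raises, naming the components.
    """
    if isinstance(W, ConnectivityMatrix):
        A, labels = W.W, W.channel_labels
    else:
        A = np.asarray(W, dtype=float)
        labels = None
        if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be square and symmetric")
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    nz = A[iu, ju] != 0
    i_arr, j_arr, w_arr = iu[nz], ju[nz], A[iu, ju][nz]
    order = np.lexsort((j_arr, i_arr, -w_arr))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for idx in order:
        i, j, w = int(i_arr[idx]), int(j_arr[idx]), float(w_arr[idx])
        if uf.union(i, j):
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        comps: dict[int, list[int]] = {}
        for v in range(n):
            comps.setdefault(uf.find(v), []).append(v)
        raise ValueError(
            f"graph is disconnected; components: {sorted(comps.values())}"
        )
    return SpanningTree(n, edges, labels)


def mst_metrics(T: SpanningTree) -> MSTMetricsRecord:
    """The six normalised tree metrics of a spanning tree (N >= 3)."""
    n = T.n_nodes
    if n < 3:
        raise ValueError("tree metrics need at least 3 nodes")
    m = n - 1
    g = T.to_networkx()
    degrees = np.array([d for _, d in g.degree()])
    leaves = int((degrees == 1).sum())
    ecc = nx.eccentricity(g)  # hop counts (edges ignored as weights)
    ecc_vals = np.array(list(ecc.values()), dtype=float)
    diameter = float(ecc_vals.max())
    bc_norm = max(nx.betweenness_centrality(g, normalized=True).values())
    lf = leaves / m
    return MSTMetricsRecord(
        k_max=float(degrees.max()) / m,
        bc=float(bc_norm),
        ecc=float(ecc_vals.mean()) / m,
        diameter=diameter / m,
        leaf_fraction=lf,
        tree_hierarchy=lf / (2 * bc_norm),
    )
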