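"""Proportional thresholding and classical weighted graph metrics.

All metrics operate on a symmetric nonnegative weighted adjacency matrix with
zero diagonal.  Path-based metrics convert weights to lengths as
``d = 1/W`` (strong connections are short paths).  Clustering is the plain
triple-product weighted form

    C_i = sum_{k!=i} sum_{l!=i,k} W_ik W_il W_kl / sum_{k!=i} sum_{l!=i,k} W_ik W_il

(the cube-root Onnela variant is available via ``variant="onnela"``).
Normalised metrics divide by the mean over weight-reshuffled surrogate
networks: gamma = C/C_random, lambda = L/L_random, small-world sigma =
gamma/lambda.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "ThresholdedGraph",
    "GraphMetricsRecord",
    "proportional_threshold",
    "node_degrees",
    "clustering_coefficients",
    "local_efficiency",
    "path_length",
    "global_efficiency",
    "random_surrogates",
    "normalized_metrics",
    "graph_metrics_record",
]

logger = logging.getLogger(__name__)


@dataclass
class ThresholdedGraph:
    """Weighted adjacency after keeping the top proportion of connections."""

    W: np.ndarray
    proportion: float
    n_retained: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class GraphMetricsRecord:
    """Per-subject, per-band classical graph metrics."""

    mean_connectivity: float
    degree_mean: float
    clustering: float
    clustering_norm: float  # gamma = C / C_random
    local_efficiency: float
    path_length: float
    path_length_norm: float  # lambda = L / L_random
    global_efficiency: float
    sigma: float  # gamma / lambda

    def to_dict(self) -> dict[str, float]:
        return {
            "mean_connectivity": self.mean_connectivity,
            "degree_mean": self.degree_mean,
            "clustering": self.clustering,
            "clustering_norm": self.clustering_norm,
            "local_efficiency": self.local_efficiency,
            "path_length": self.path_length,
            "path_length_norm": self.path_length_norm,
            "global_efficiency": self.global_efficiency,
            "sigma": self.sigma,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def proportional_threshold(W: ConnectivityMatrix | np.ndarray, p: float) -> ThresholdedGraph:
    """Retain the top ``round(p * E)`` strongest connections, ``E = N(N-1)/2``.

    Negative weights rank below all positive ones (zeroed first).  Ties at
    the cut are broken deterministically by (i, j) lexicographic order.
    """
    if not (0 < p <= 1):
        raise ValueError("threshold proportion must lie in (0, 1]")
    A = W.W if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = A[iu, ju]
    n_edges = weights.size
    k = _round_half_away(p * n_edges)
    # stable sort on (-w, i, j): lexsort keys are read last-to-first
    order = np.lexsort((ju, iu, -weights))
    keep = order[:k]
    if k < n_edges and weights[order[k - 1]] == weights[order[k]]:
        logger.info(
            "proportional_threshold: tie at the cut (weight %g) broken "
            "lexicographically",
            weights[order[k]],
        )
    out = np.zeros_like(A)
    out[iu[keep], ju[keep]] = weights[keep]
    out = out + out.T
    return ThresholdedGraph(out, p, k)


def node_degrees(G: ThresholdedGraph) -> tuple[np.ndarray, float]:
    """Weighted degree K_i = sum_j W_ij per node, and the mean over nodes."""
    K = G.W.sum(axis=1)
    return K, float(K.mean())


def clustering_coefficients(
    G: ThresholdedGraph, variant: str = "as_printed"
) -> tuple[np.ndarray, float]:
    """Per-node weighted clustering C_i and the network average C.

    ``as_printed``: C_i = (W^3)_ii / (K_i^2 - sum_k W_ik^2), i.e. the
    triple-product form with no exponent; ``onnela``: geometric-mean triangle
    intensity normalised by the binary degree, k_i(k_i - 1).
    C_i = 0 where the denominator vanishes.
    """
    W = G.W
    if variant == "as_printed":
        num = np.einsum("ij,jk,ki->i", W, W, W)
        K = W.sum(axis=1)
        den = K**2 - (W**2).sum(axis=1)
    elif variant == "onnela":
        Wr = np.cbrt(W)
        num = np.einsum("ij,jk,ki->i", Wr, Wr, Wr)
        k = (W > 0).sum(axis=1).astype(float)
        den = k * (k - 1)
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return C, float(C.mean())


def _length_matrix(W: np.ndarray) -> csr_matrix:
    """Edge lengths 1/W as a sparse matrix (absent where W == 0)."""
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    return csr_matrix(L)


def _all_pairs_distances(W: np.ndarray) -> np.ndarray:
    return shortest_path(_length_matrix(W), method="D", directed=False)


def local_efficiency(G: ThresholdedGraph) -> float:
    """Average local efficiency.

    For each node i with binary degree k_i >= 2, neighbour pairs (j, h)
    contribute (W_ij W_ih / d_jh(N_i))^(1/3), where d_jh(N_i) is the shortest
    1/W-length path between j and h restricted to i's neighbourhood; the node
    sum is divided by k_i (k_i - 1), and the network value carries a 1/(2N)
    prefactor (ordered neighbour pairs are counted twice).  Nodes with fewer
    than 2 neighbours contribute 0.
    """
    W = G.W
    n = G.n_nodes
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(W[i])[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        d = _all_pairs_distances(sub)
        wi = W[i, nbrs]
        prod = np.outer(wi, wi)  # W_ij * W_ih
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.cbrt(prod / d)
        np.fill_diagonal(contrib, 0.0)
        contrib[~np.isfinite(contrib)] = 0.0  # disconnected within N_i
        total += contrib.sum() / (k * (k - 1))
    return total / (2 * n)


def path_length(G: ThresholdedGraph) -> float:
    """Characteristic path length: mean shortest 1/W-length over connected
    node pairs (disconnected pairs are excluded and their count logged)."""
    if not np.any(G.W > 0):
        raise ValueError("path length undefined for a graph with no edges")
    d = _all_pairs_distances(G.W)
    off = ~np.eye(G.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int((off & ~np.isfinite(d)).sum())
    if n_excluded:
        logger.info("path_length: %d disconnected ordered pair(s) excluded", n_excluded)
    if not finite.any():
        raise ValueError("no connected node pairs")
    return float(d[finite].mean())


def global_efficiency(G: ThresholdedGraph) -> float:
    """Mean inverse shortest path over ordered pairs, with 1/inf = 0."""
    n = G.n_nodes
    if n < 2:
        return 0.0
    if not np.any(G.W > 0):
        return 0.0
    d = _all_pairs_distances(G.W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def random_surrogates(
    G: ThresholdedGraph, count: int, seed: int | np.random.Generator
) -> list[ThresholdedGraph]:
    """Weight-reshuffled surrogate networks.

    Each surrogate permutes the upper-triangle weight multiset uniformly at
    random and mirrors it, preserving symmetry, the zero diagonal and the
    exact weight multiset.
    """
    if count < 1:
        raise ValueError("surrogate count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = G.n_nodes
    iu = np.triu_indices(n, k=1)
    weights = G.W[iu]
    out = []
    for _ in range(count):
        perm = rng.permutation(weights)
        S = np.zeros_like(G.W)
        S[iu] = perm
        out.append(ThresholdedGraph(S + S.T, G.proportion, G.n_retained))
    return out


def normalized_metrics(
    G: ThresholdedGraph,
    surrogates: list[ThresholdedGraph],
    variant: str = "as_printed",
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against the surrogate ensemble means."""
    if not surrogates:
        raise ValueError("need at least one surrogate")
    _, C = clustering_coefficients(G, variant)
    L = path_length(G)
    C_rand = float(np.mean([clustering_coefficients(s, variant)[1] for s in surrogates]))
    L_rand = float(np.mean([path_length(s) for s in surrogates]))
    if C_rand == 0 or L_rand == 0:
        raise ValueError(
            "surrogate normalisation undefined (C_random or L_random is 0); "
            "the thresholded graph is too sparse for reshuffled surrogates to "
            "form triangles — raise threshold_prop or use more nodes"
        )
    gamma = C / C_rand
    lam = L / L_rand
    return gamma, lam, gamma / lam


def graph_metrics_record(
    W: ConnectivityMatrix,
    p: float = 0.10,
    n_surrogates: int = 50,
    seed: int | np.random.Generator = 0,
    variant: str = "as_printed",
) -> GraphMetricsRecord:
    """Full classical-metric record for one connectivity matrix."""
    G = proportional_threshold(W, p)
    _, K_mean = node_degrees(G)
    _, C = clustering_coefficients(G, variant)
    LE = local_efficiency(G)
    L = path_length(G)
    GE = global_efficiency(G)
    surr = random_surrogates(G, n_surrogates, seed)
    gamma, lam, sigma = normalized_metrics(G, surr, variant)
    return GraphMetricsRecord(
        mean_connectivity=W.global_mean(),
        degree_mean=K_mean,
        clustering=C,
        clustering_norm=gamma,
        local_efficiency=LE,
        path_length=L,
        path_length_norm=lam,
        global_efficiency=GE,
        sigma=sigma,
    )
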