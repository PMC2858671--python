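"""Wiring-cost statistics and the minimally rewired baseline.

The mean connection distance L̄ is the average Euclidean edge length
expressed in units of the node-to-node spacing δ (the mean nearest-neighbour
distance), making it dimensionless and comparable across systems.  For a
network of N nodes whose interconnect topology has fractal dimension
D_T > D_E, wiring-length theory for cost-efficient embeddings predicts

    L̄ = κ · N^(1/D_E − 1/D_T),

with κ of order unity when the embedding is cost-efficient.  Inverting this
relation on the observed L̄ yields the cost-efficiency coefficient κ.

The minimally rewired baseline keeps node positions fixed and replaces the
edge set by the Euclidean minimum spanning tree plus the shortest remaining
candidate edges until the original edge count is restored — the cheapest
connected wiring at matched density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .network import SpatialNetwork

__all__ = [
    "node_spacing",
    "mean_connection_distance",
    "cost_efficiency_kappa",
    "rewire_minimal",
    "wiring_report",
    "WiringReport",
]


def node_spacing(net: SpatialNetwork) -> float:
    """Node-to-node spacing δ: mean distance from a node to its nearest neighbour.

    Strictly positive and homogeneous of degree 1 in the coordinates (scaling
    all coordinates by c scales δ by c).  Coincident nodes make the spacing
    degenerate and raise an error.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    nn = cKDTree(net.coords).query(net.coords, k=2)[0][:, 1]
    if np.any(nn <= 0):
        raise ValueError("coincident nodes: node spacing is degenerate")
    return float(nn.mean())


def mean_connection_distance(net: SpatialNetwork) -> float:
    """Mean Euclidean edge length in units of the node spacing (dimensionless L̄)."""
    if net.n_edges < 1:
        raise ValueError("need at least one edge")
    return float(net.edge_lengths().mean()) / node_spacing(net)


def cost_efficiency_kappa(L_bar: float, N: int, D_T: float, D_E: int) -> float:
    """Cost-efficiency coefficient κ = L̄ / N^(1/D_E − 1/D_T), for D_T > D_E.

    κ near 1 indicates a cost-efficient embedding; the relation only holds in
    the regime where the topology is higher-dimensional than the embedding
    space.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not D_T > D_E:
        raise ValueError(
            f"kappa is defined for D_T > D_E (got D_T={D_T:.3g}, D_E={D_E}); "
            "lattice-like networks with D_T <= D_E are outside this regime"
        )
    predicted = float(N) ** (1.0 / D_E - 1.0 / D_T)
    return float(L_bar) / predicted


def _euclidean_mst_edges(coords: np.ndarray) -> np.ndarray:
    d = squareform(pdist(coords))
    mst = minimum_spanning_tree(d)
    rows, cols = mst.nonzero()
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    return np.stack([lo, hi], axis=1).astype(np.int64)


def rewire_minimal(net: SpatialNetwork, knn: int = 50) -> SpatialNetwork:
    """Cheapest connected rewiring at matched density, positions fixed.

    The Euclidean minimum spanning tree guarantees connectivity; remaining
    candidate pairs are then added in ascending distance order (ties broken
    lexicographically) until the edge count matches the input.  For networks
    beyond 5000 nodes the candidate set is restricted to each node's ``knn``
    nearest neighbours to keep memory linear.
    """
    n, m = net.n_nodes, net.n_edges
    if n < 2:
        raise ValueError("need at least 2 nodes")
    tree_edges = _euclidean_mst_edges(net.coords)
    if m <= tree_edges.shape[0]:
        return net.replace_edges(tree_edges)

    taken = set(map(tuple, tree_edges.tolist()))
    if n <= 5000:
        iu, ju = np.triu_indices(n, k=1)
    else:
        _, idx = cKDTree(net.coords).query(net.coords, k=knn + 1)
        pairs = set()
        for i in range(n):
            for j in idx[i, 1:]:
                pairs.add((min(i, int(j)), max(i, int(j))))
        arr = np.array(sorted(pairs), dtype=np.int64)
        iu, ju = arr[:, 0], arr[:, 1]
    d = np.sqrt(((net.coords[iu] - net.coords[ju]) ** 2).sum(axis=1))
    order = np.lexsort((ju, iu, d))
    edges = list(map(tuple, tree_edges.tolist()))
    for k in order:
        if len(edges) >= m:
            break
        pair = (int(iu[k]), int(ju[k]))
        if pair in taken:
            continue
        taken.add(pair)
        edges.append(pair)
    if len(edges) < m:
        raise RuntimeError("candidate edge set too small; increase knn")
    return net.replace_edges(np.array(edges, dtype=np.int64))


@dataclass
class WiringReport:
    """Wiring-cost summary for one network."""

    delta: float                 # node-to-node spacing (coordinate units)
    L_bar: float                 # mean connection distance in spacing units
    mean_edge_length: float      # raw mean edge length (coordinate units)
    total_edge_length: float     # raw total wiring (coordinate units)
    kappa: float | None          # cost-efficiency coefficient; None if D_T <= D_E


def wiring_report(net: SpatialNetwork, D_T: float | None = None) -> WiringReport:
    """Compute δ, L̄, raw wiring cost and (when D_T > D_E is known) κ."""
    delta = node_spacing(net)
    lengths = net.edge_lengths()
    l_bar = float(lengths.mean()) / delta
    kappa = None
    if D_T is not None and D_T > net.embedding_dim:
        kappa = cost_efficiency_kappa(l_bar, net.n_nodes, D_T, net.embedding_dim)
    return WiringReport(
        delta=delta,
        L_bar=l_bar,
        mean_edge_length=float(lengths.mean()),
        total_edge_length=float(lengths.sum()),
        kappa=kappa,
    )
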