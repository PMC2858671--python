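"""Spatially embedded networks: container, file I/O and matrix-to-network rules.

The universal input object of the package is a :class:`SpatialNetwork`: an
undirected simple graph whose nodes carry coordinates in 2- or 3-dimensional
Euclidean space.  Connectome-style weighted matrices (inter-regional
correlations, tract probabilities) are turned into such networks either by
thresholding or by backbone extraction (maximum-weight spanning tree plus
strongest edges up to a target mean degree).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class NetworkError(ValueError):
    """Raised for structurally invalid networks or malformed input files."""


def _canonical_edges(edges: np.ndarray, n_nodes: int, *, allow_self_loops: bool = False) -> np.ndarray:
    """Sort endpoints, drop duplicates, validate index range; (m, 2) int array."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size == 0:
        return edges.reshape(0, 2)
    if edges.min() < 0 or edges.max() >= n_nodes:
        raise NetworkError("edge endpoint out of range")
    if not allow_self_loops and np.any(edges[:, 0] == edges[:, 1]):
        bad = edges[edges[:, 0] == edges[:, 1]][0, 0]
        raise NetworkError(f"self-loop on node index {bad} is not allowed")
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    stacked = np.stack([lo, hi], axis=1)
    return np.unique(stacked, axis=0)


class SpatialNetwork:
    """Undirected simple graph with node coordinates in Euclidean space.

    Parameters
    ----------
    node_ids
        Ordered node labels (opaque strings).
    coords
        Array of shape (N, D_E) with D_E in {2, 3}; finite entries.
    edges
        Integer index pairs into ``node_ids``; symmetric duplicates are
        collapsed and self-loops rejected.
    """

    def __init__(self, node_ids: Sequence[str], coords: np.ndarray, edges: np.ndarray):
        self.node_ids: list[str] = [str(x) for x in node_ids]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkError("duplicate node ids")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] != len(self.node_ids):
            raise NetworkError("coords must be an (N, D_E) array matching node_ids")
        if coords.shape[1] not in (2, 3):
            raise NetworkError(f"embedding dimension must be 2 or 3, got {coords.shape[1]}")
        if not np.all(np.isfinite(coords)):
            raise NetworkError("non-finite coordinate")
        if coords.shape[0] < 1:
            raise NetworkError("network needs at least one node")
        self.coords = coords
        self.edges = _canonical_edges(edges, len(self.node_ids))
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    # -- basic measures -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def embedding_dim(self) -> int:
        """Euclidean embedding dimension D_E."""
        return int(self.coords.shape[1])

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def index_of(self, node_id: str) -> int:
        return self._index[str(node_id)]

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every edge, in coordinate units."""
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        return np.sqrt((d * d).sum(axis=1))

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))

    def adjacency_sparse(self):
        m = self.n_edges
        data = np.ones(2 * m)
        rows = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)).tocsr()

    def connected_components(self) -> tuple[int, np.ndarray]:
        if self.n_edges == 0:
            return self.n_nodes, np.arange(self.n_nodes)
        return connected_components(self.adjacency_sparse(), directed=False)

    def is_connected(self) -> bool:
        return self.connected_components()[0] == 1

    # -- conversions ----------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, nid in enumerate(self.node_ids):
            g.add_node(nid, pos=tuple(self.coords[i]))
        g.add_edges_from((self.node_ids[u], self.node_ids[v]) for u, v in self.edges)
        return g

    def to_igraph(self):
        import igraph

        return igraph.Graph(n=self.n_nodes, edges=[(int(u), int(v)) for u, v in self.edges])

    def replace_edges(self, edges: np.ndarray) -> "SpatialNetwork":
        """New network with identical nodes/coordinates and a new edge set."""
        return SpatialNetwork(self.node_ids, self.coords, edges)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SpatialNetwork N={self.n_nodes} m={self.n_edges} "
            f"D_E={self.embedding_dim} density={self.density:.4f}>"
        )

    # -- serialisation --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": self.node_ids,
            "coords": self.coords.tolist(),
            "edges": [[self.node_ids[u], self.node_ids[v]] for u, v in self.edges],
            "embedding_dim": self.embedding_dim,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SpatialNetwork":
        doc = json.loads(text)
        index = {nid: i for i, nid in enumerate(doc["nodes"])}
        edges = np.array([[index[a], index[b]] for a, b in doc["edges"]], dtype=np.int64).reshape(-1, 2)
        return cls(doc["nodes"], np.asarray(doc["coords"], dtype=float), edges)


# ---------------------------------------------------------------------------
# file I/O: whitespace/tab delimited text with optional '#' comment lines
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterable[list[str]]:
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                yield line.split()


def read_spatial_network(edge_path, coord_path) -> SpatialNetwork:
    """Read a network from an edge-list file and a coordinate file.

    The coordinate file has rows ``node_id x y [z]`` (consistent arity; the
    embedding dimension is inferred from the column count).  The edge file has
    two node-id columns; ``a b`` and ``b a`` collapse to a single edge.
    """
    node_ids: list[str] = []
    rows: list[list[float]] = []
    arity: int | None = None
    for parts in _data_lines(coord_path):
        if arity is None:
            arity = len(parts)
            if arity not in (3, 4):
                raise NetworkError(
                    f"coordinate rows must be 'id x y' or 'id x y z', got {len(parts)} columns"
                )
        elif len(parts) != arity:
            raise NetworkError(
                f"inconsistent coordinate arity: row for '{parts[0]}' has {len(parts)} "
                f"columns, expected {arity}"
            )
        node_ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise NetworkError(f"non-numeric coordinate for node '{parts[0]}'") from exc
    if arity is None:
        raise NetworkError(f"coordinate file {coord_path} is empty")

    index = {nid: i for i, nid in enumerate(node_ids)}
    pairs: list[tuple[int, int]] = []
    for parts in _data_lines(edge_path):
        if len(parts) != 2:
            raise NetworkError(f"edge rows must have two columns, got {parts}")
        a, b = parts
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise NetworkError(f"unknown node id '{missing}' in edge file")
        if a == b:
            raise NetworkError(f"self-loop on node '{a}' rejected")
        pairs.append((index[a], index[b]))
    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    return SpatialNetwork(node_ids, np.asarray(rows, dtype=float), edges)


def write_spatial_network(net: SpatialNetwork, edge_path, coord_path, header: str | None = None) -> None:
    """Write the standard edge-list + coordinate text files (round-trip exact)."""
    with open(coord_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for nid, xyz in zip(net.node_ids, net.coords):
            fh.write(nid + "\t" + "\t".join(repr(float(x)) for x in xyz) + "\n")
    with open(edge_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for u, v in net.edges:
            fh.write(f"{net.node_ids[u]}\t{net.node_ids[v]}\n")


# ---------------------------------------------------------------------------
# weighted matrices
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Symmetric weight matrix (correlation or connection probability).

    The diagonal is ignored by all constructions.
    """

    labels: list[str]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if self.W.shape != (n, n):
            raise NetworkError("weight matrix shape does not match labels")
        if not np.all(np.isfinite(self.W)):
            raise NetworkError("non-finite weight")
        if not np.allclose(self.W, self.W.T, atol=1e-9, rtol=0.0):
            raise NetworkError("weight matrix is not symmetric within 1e-9")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def read_csv(cls, path) -> "WeightMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.W, index=self.labels, columns=self.labels).to_csv(path)


class ThresholdResult(NamedTuple):
    edges: np.ndarray           # (m, 2) index pairs
    threshold: float            # the tau actually applied (strict '>')
    achieved_density: float


def threshold_matrix(
    wm: WeightMatrix,
    tau: float | None = None,
    density: float | None = None,
) -> ThresholdResult:
    """Binarize a weight matrix by absolute threshold or target density.

    Exactly one of ``tau`` / ``density`` must be given.  An edge (i, j) exists
    iff W_ij > tau (strict).  The density rule picks the smallest tau whose
    suprathreshold density is at least ``density``; weights tied at the cut
    value are all included and the achieved density is reported.
    """
    if (tau is None) == (density is None):
        raise ValueError("give exactly one of tau= or density=")
    iu, ju = np.triu_indices(wm.n, k=1)
    w = wm.W[iu, ju]
    total = w.size
    if total == 0:
        raise NetworkError("matrix has no off-diagonal pairs")
    if density is not None:
        if not 0.0 < density <= 1.0:
            raise ValueError("target density must be in (0, 1]")
        q = int(np.ceil(density * total))
        order = np.sort(w)[::-1]
        cut_value = order[q - 1]
        if np.all(w == w[0]):
            warnings.warn(
                "all off-diagonal weights equal: density rule is ambiguous, "
                "including every pair (tie rule)",
                stacklevel=2,
            )
        keep = w >= cut_value
        tau_used = float(np.nextafter(cut_value, -np.inf))
    else:
        keep = w > tau
        tau_used = float(tau)
    edges = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)
    achieved = edges.shape[0] / total
    return ThresholdResult(edges, tau_used, achieved)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def backbone_extraction(wm: WeightMatrix, target_mean_degree: float = 4.0) -> np.ndarray:
    """Connectivity backbone: maximum-weight spanning tree plus strongest edges.

    The spanning tree over positive weights guarantees connectivity; remaining
    edges are then added in descending weight order (ties broken
    lexicographically) until the mean degree 2m/N reaches
    ``target_mean_degree``.  This is the construction used for tract
    probability matrices with a target mean degree of 4.
    """
    n = wm.n
    iu, ju = np.triu_indices(n, k=1)
    w = wm.W[iu, ju]
    if np.any(w < 0):
        raise NetworkError("backbone extraction requires nonnegative weights")
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]

    # connectivity of the positive-weight graph
    adj = coo_matrix((np.ones(w.size), (iu, ju)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise NetworkError(
            f"positive-weight graph is disconnected: {n_comp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)[:10]}"
        )

    # deterministic order: descending weight, then lexicographic pair
    order = np.lexsort((ju, iu, -w))
    iu, ju, w = iu[order], ju[order], w[order]

    uf = _UnionFind(n)
    in_tree = np.zeros(w.size, dtype=bool)
    n_tree = 0
    for idx in range(w.size):
        if uf.union(int(iu[idx]), int(ju[idx])):
            in_tree[idx] = True
            n_tree += 1
            if n_tree == n - 1:
                break

    keep = in_tree.copy()
    m = n_tree
    target_m = int(np.ceil(target_mean_degree * n / 2.0))
    if m < target_m:
        for idx in range(w.size):
            if not keep[idx]:
                keep[idx] = True
                m += 1
                if m >= target_m:
                    break
    edges = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)
    return _canonical_edges(edges, n)
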