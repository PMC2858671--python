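"""Hierarchical modularity: detection, null-model testing, decomposition.

Community structure is found with the Louvain algorithm; its modularity Q is
tested against two 100-sample null ensembles — pure random graphs with the
same (N, m), and "functional" random graphs with the same degree sequence
(Maslov–Sneppen rewiring, 15 accepted swaps per edge) — with a 1-tailed test
of whether the observed Q exceeds the null distribution.  Modules passing
both tests are recursively decomposed, giving a tree whose depth counts the
significant hierarchical levels.  A Louvain-consensus co-classification
matrix visualises the nesting (a lightweight stand-in for full hierarchical
co-classification; no quantitative claim rests on it).

Heavy loops (Louvain, G(n, m) sampling) run in igraph's C core, seeded
through Python's ``random`` module; degree-preserving nulls use the compiled
swap kernel shared with :mod:`netrent.synth`.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy import stats

from ._rewire import maslov_rewire
from .network import SpatialNetwork

__all__ = [
    "louvain_partition",
    "modularity_significance",
    "hierarchical_decompose",
    "coclassification",
    "ModuleNode",
    "ModuleTree",
    "SignificanceResult",
    "CoclassMatrix",
]


def _as_graph(net_or_edges, n_nodes=None):
    if isinstance(net_or_edges, SpatialNetwork):
        return net_or_edges.edges, net_or_edges.n_nodes
    edges = np.asarray(net_or_edges, dtype=np.int64).reshape(-1, 2)
    if n_nodes is None:
        n_nodes = int(edges.max()) + 1 if edges.size else 0
    return edges, int(n_nodes)


def _igraph_from(edges: np.ndarray, n: int) -> igraph.Graph:
    return igraph.Graph(n=n, edges=np.asarray(edges, dtype=np.int64).tolist())


def _louvain_best(g: igraph.Graph, rng: random.Random, runs: int):
    """Best-of-``runs`` Louvain partitions (membership array, Q)."""
    best_q = -np.inf
    best_mem = None
    for _ in range(max(1, runs)):
        random.seed(rng.getrandbits(31))
        part = g.community_multilevel()
        q = part.modularity
        if q > best_q:
            best_q = q
            best_mem = np.asarray(part.membership, dtype=np.int64)
    return best_mem, float(best_q)


def louvain_partition(net_or_edges, n_nodes=None, seed: int | None = None, runs: int = 20):
    """Louvain community detection; returns (list of node-index sets, Q).

    The best modularity over ``runs`` seeded restarts is kept.  Q follows the
    usual definition sum_c [e_c/m - (d_c/2m)^2].
    """
    edges, n = _as_graph(net_or_edges, n_nodes)
    if edges.shape[0] < 1:
        raise ValueError("empty edge set: modularity undefined")
    g = _igraph_from(edges, n)
    rng = random.Random(seed)
    mem, q = _louvain_best(g, rng, runs)
    part = [set(np.flatnonzero(mem == c).tolist()) for c in range(mem.max() + 1)]
    part = [p for p in part if p]
    return part, q


@dataclass
class SignificanceResult:
    Q: float
    p_func: float
    p_rand: float
    null_func_mean: float
    null_func_sd: float
    null_rand_mean: float
    null_rand_sd: float
    n_null: int
    membership: np.ndarray = field(repr=False)
    degenerate: bool = False


def _one_tailed_p(q_obs: float, nulls: np.ndarray) -> tuple[float, bool]:
    """P(single null draw >= Q_obs) via a t prediction bound.

    t = (Q_obs - mean)/(sd * sqrt(1 + 1/n)); small p means the observed
    modularity is higher than the null distribution.  Degenerate (zero
    variance) nulls fall back to an exceedance count.
    """
    n = nulls.size
    sd = float(nulls.std(ddof=1)) if n > 1 else 0.0
    if sd <= max(1e-12, 1e-9 * abs(float(nulls.mean()))) or not np.isfinite(sd):
        p = (np.count_nonzero(nulls >= q_obs) + 1) / (n + 1)
        return float(p), True
    t = (q_obs - float(nulls.mean())) / (sd * math.sqrt(1.0 + 1.0 / n))
    return float(stats.t.sf(t, df=n - 1)), False


def modularity_significance(
    net_or_edges,
    n_nodes=None,
    n_null: int = 100,
    seed: int | None = None,
    runs: int = 1,
    swaps_per_edge: float = 15.0,
) -> SignificanceResult:
    """Test observed modularity against pure-random and degree-matched nulls.

    The same number of Louvain ``runs`` is used for the observed network and
    for every surrogate, so the comparison is exchangeable under the null.
    """
    if n_null < 10:
        raise ValueError("need at least 10 null samples")
    edges, n = _as_graph(net_or_edges, n_nodes)
    if edges.shape[0] < 1:
        raise ValueError("empty edge set")
    m = edges.shape[0]
    rng = random.Random(seed)
    g = _igraph_from(edges, n)
    mem, q_obs = _louvain_best(g, rng, runs)

    n_swaps = int(math.ceil(swaps_per_edge * m))
    q_func = np.empty(n_null)
    q_rand = np.empty(n_null)
    for i in range(n_null):
        rew, _ = maslov_rewire(edges, n, n_swaps, rng.getrandbits(31))
        _, q_func[i] = _louvain_best(_igraph_from(rew, n), rng, runs)
        random.seed(rng.getrandbits(31))
        g_r = igraph.Graph.Erdos_Renyi(n=n, m=m)
        _, q_rand[i] = _louvain_best(g_r, rng, runs)

    p_func, deg_f = _one_tailed_p(q_obs, q_func)
    p_rand, deg_r = _one_tailed_p(q_obs, q_rand)
    if deg_f or deg_r:
        warnings.warn("degenerate null variance: p from exceedance count", stacklevel=2)
    return SignificanceResult(
        Q=q_obs,
        p_func=p_func,
        p_rand=p_rand,
        null_func_mean=float(q_func.mean()),
        null_func_sd=float(q_func.std(ddof=1)),
        null_rand_mean=float(q_rand.mean()),
        null_rand_sd=float(q_rand.std(ddof=1)),
        n_null=n_null,
        membership=mem,
        degenerate=deg_f or deg_r,
    )


@dataclass
class ModuleNode:
    members: np.ndarray
    depth: int
    Q: float | None = None
    p_func: float | None = None
    p_rand: float | None = None
    significant: bool = False
    children: list["ModuleNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "size": int(self.members.size),
            "members": [int(x) for x in self.members],
            "depth": self.depth,
            "Q": self.Q,
            "p_func": self.p_func,
            "p_rand": self.p_rand,
            "significant": self.significant,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class ModuleTree:
    """Dendrogram of significance-tested modules; root covers all nodes."""

    root: ModuleNode
    alpha: float

    def depth(self) -> int:
        def walk(node: ModuleNode) -> int:
            if not node.children:
                return node.depth
            return max(walk(c) for c in node.children)

        return walk(self.root)

    def n_significant_levels(self) -> int:
        return self.depth()

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "depth": self.depth(), "tree": self.root.to_dict()}


def hierarchical_decompose(
    net_or_edges,
    n_nodes=None,
    alpha: float = 0.05,
    min_module_size: int = 8,
    n_null: int = 100,
    seed: int | None = None,
    runs: int = 1,
    partition_runs: int = 10,
    max_depth: int = 10,
) -> ModuleTree:
    """Iterative modular decomposition with per-module null-model testing.

    Each module's induced subnetwork is partitioned; if its modularity beats
    both null ensembles (matched to the subnetwork's own size, density and
    degree sequence) at level ``alpha``, the sub-modules become children and
    are decomposed in turn.  Modules smaller than ``min_module_size`` are
    leaves.  The tree depth is the number of significant hierarchical levels
    (a non-modular network has depth 1).
    """
    edges, n = _as_graph(net_or_edges, n_nodes)
    rng = random.Random(seed)

    def decompose(members: np.ndarray, depth: int) -> ModuleNode:
        node = ModuleNode(members=members, depth=depth)
        if members.size < max(min_module_size, 3) or depth >= max_depth:
            return node
        inside = np.zeros(n, dtype=bool)
        inside[members] = True
        sub_mask = inside[edges[:, 0]] & inside[edges[:, 1]]
        local = -np.ones(n, dtype=np.int64)
        local[members] = np.arange(members.size)
        sub_edges = local[edges[sub_mask]]
        if sub_edges.shape[0] < 2:
            return node
        sig = modularity_significance(
            sub_edges, members.size, n_null=n_null, seed=rng.getrandbits(31), runs=runs
        )
        node.Q = sig.Q
        node.p_func = sig.p_func
        node.p_rand = sig.p_rand
        if not (sig.p_func < alpha and sig.p_rand < alpha):
            return node
        # membership for the recursion from a more thorough search
        mem, _ = _louvain_best(
            _igraph_from(sub_edges, members.size), rng, partition_runs
        )
        n_comm = int(mem.max()) + 1
        if n_comm < 2:
            return node
        node.significant = True
        for c in range(n_comm):
            child_members = members[np.flatnonzero(mem == c)]
            if child_members.size == 0:
                continue
            node.children.append(decompose(child_members, depth + 1))
        return node

    root = decompose(np.arange(n), 1)
    return ModuleTree(root=root, alpha=alpha)


@dataclass
class CoclassMatrix:
    """Consensus co-classification frequencies with a display ordering."""

    matrix: np.ndarray
    order: np.ndarray

    def reordered(self) -> np.ndarray:
        return self.matrix[np.ix_(self.order, self.order)]

    def to_csv(self, path, labels=None) -> None:
        import pandas as pd

        labels = labels if labels is not None else [str(i) for i in range(self.matrix.shape[0])]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path)


def coclassification(
    net_or_edges,
    n_nodes=None,
    runs: int = 100,
    seed: int | None = None,
    max_depth: int = 4,
) -> CoclassMatrix:
    """Louvain-consensus co-classification matrix.

    Entry (i, j) is the fraction of seeded hierarchical Louvain runs in which
    i and j share a module, averaged with equal weight over hierarchical
    depths within each run.  Nested modular structure shows up as layered
    blocks along the diagonal.  Node order for display is the average-linkage
    leaf order of the co-classification distances.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs")
    edges, n = _as_graph(net_or_edges, n_nodes)
    rng = random.Random(seed)
    acc = np.zeros((n, n))

    for _ in range(runs):
        labels_per_depth: list[np.ndarray] = []
        current = [np.arange(n)]
        for _depth in range(max_depth):
            labels = np.zeros(n, dtype=np.int64)
            nxt: list[np.ndarray] = []
            next_label = 0
            split_any = False
            for members in current:
                if members.size < 4:
                    labels[members] = next_label
                    next_label += 1
                    nxt.append(members)
                    continue
                inside = np.zeros(n, dtype=bool)
                inside[members] = True
                sub_mask = inside[edges[:, 0]] & inside[edges[:, 1]]
                local = -np.ones(n, dtype=np.int64)
                local[members] = np.arange(members.size)
                sub_edges = local[edges[sub_mask]]
                if sub_edges.shape[0] < 1:
                    labels[members] = next_label
                    next_label += 1
                    nxt.append(members)
                    continue
                mem, q = _louvain_best(_igraph_from(sub_edges, members.size), rng, 1)
                if q <= 0.05 or mem.max() == 0:
                    labels[members] = next_label
                    next_label += 1
                    nxt.append(members)
                    continue
                split_any = True
                for c in range(int(mem.max()) + 1):
                    child = members[np.flatnonzero(mem == c)]
                    if child.size:
                        labels[child] = next_label
                        next_label += 1
                        nxt.append(child)
            labels_per_depth.append(labels)
            current = nxt
            if not split_any:
                break
        run_acc = np.zeros((n, n))
        for labels in labels_per_depth:
            run_acc += labels[:, None] == labels[None, :]
        acc += run_acc / len(labels_per_depth)

    mat = acc / runs
    np.fill_diagonal(mat, 1.0)
    order = _linkage_order(mat)
    return CoclassMatrix(matrix=mat, order=order)


def _linkage_order(mat: np.ndarray) -> np.ndarray:
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    n = mat.shape[0]
    if n < 3:
        return np.arange(n)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    condensed = squareform(dist, checks=False)
    return np.asarray(leaves_list(linkage(condensed, method="average")), dtype=np.int64)
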