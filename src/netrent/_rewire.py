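"""Compiled Maslov–Sneppen double-edge-swap kernel.

Dense uint8 adjacency keeps membership tests O(1); memory is N^2 bytes, which
is fine at the network sizes this package targets (N up to a few thousand).
The kernel counts *accepted* swaps toward the budget; proposals creating
self-loops or multi-edges are rejected and retried.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _maslov_kernel(edges: np.ndarray, adj: np.ndarray, n_target: int, max_attempts: int, seed: int) -> int:
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    attempts = 0
    while accepted < n_target and attempts < max_attempts:
        attempts += 1
        i = np.random.randint(0, m)
        j = np.random.randint(0, m)
        if i == j:
            continue
        a, b = edges[i, 0], edges[i, 1]
        c, d = edges[j, 0], edges[j, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[i, 0], edges[i, 1] = a, d
        edges[j, 0], edges[j, 1] = c, b
        accepted += 1
    return accepted


def maslov_rewire(edges: np.ndarray, n_nodes: int, n_swaps: int, seed: int, attempts_per_swap: int = 40) -> tuple[np.ndarray, int]:
    """Return (rewired edge array, accepted swap count).

    ``n_swaps`` accepted double-edge swaps are attempted within a budget of
    ``attempts_per_swap * n_swaps + 1000`` proposals; graphs with no valid
    swap (stars, triangles, complete graphs) come back unchanged.
    """
    edges = np.ascontiguousarray(edges, dtype=np.int64).copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    adj[edges[:, 0], edges[:, 1]] = 1
    adj[edges[:, 1], edges[:, 0]] = 1
    max_attempts = attempts_per_swap * int(n_swaps) + 1000
    accepted = _maslov_kernel(edges, adj, int(n_swaps), max_attempts, int(seed) & 0x7FFFFFFF)
    return edges, int(accepted)
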