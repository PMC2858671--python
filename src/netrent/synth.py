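"""Synthetic spatial networks with known ground truth, and rewired baselines.

Four generators cover the properties the estimators in this package measure:

* ``make_lattice`` — regular grids of known topological dimension (D_T equals
  the embedding dimension; the Rent exponent of a D-dimensional lattice is
  1 - 1/D).
* ``make_hierarchical_modular`` — nested stochastic-block networks whose
  within-block connection probability rises with depth, giving fractal
  hierarchical modularity; by default blocks are also spatially nested inside
  the unit cube, emulating the spatial localisation of brain modules.
* ``make_powerlaw_scatter`` — (n, e) samples from an exact Rent law
  e = k * n**p with multiplicative log-normal noise, for estimator
  parameter-recovery experiments.
* ``rewire_random`` / ``rewire_degree_preserving`` — the two null models:
  uniformly resampled edges at fixed (N, m), and Maslov–Sneppen swaps that
  preserve the degree sequence (by default each edge is rewired on average
  15 times).  Both keep node positions untouched.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from ._rewire import maslov_rewire
from .network import NetworkError, SpatialNetwork


def _ids(n: int) -> list[str]:
    return [str(i) for i in range(n)]


def make_lattice(lengths) -> SpatialNetwork:
    """Regular lattice with nearest-neighbour (unit-distance) edges.

    ``lengths`` gives the side length per dimension (1-3 dimensions, each
    side at least 2).  Nodes sit at integer coordinates; 1-D chains are
    embedded in the plane (y = 0) since the embedding dimension is 2 or 3.
    """
    lengths = [int(x) for x in np.atleast_1d(lengths)]
    if not 1 <= len(lengths) <= 3:
        raise ValueError("lattice needs 1-3 dimension lengths")
    if any(x < 2 for x in lengths):
        raise ValueError("each lattice side must be at least 2")
    grids = np.meshgrid(*[np.arange(x) for x in lengths], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    shape = tuple(lengths)
    flat = np.arange(coords.shape[0]).reshape(shape)
    pairs = []
    for axis in range(len(lengths)):
        a = np.take(flat, np.arange(shape[axis] - 1), axis=axis).ravel()
        b = np.take(flat, np.arange(1, shape[axis]), axis=axis).ravel()
        pairs.append(np.stack([a, b], axis=1))
    edges = np.concatenate(pairs, axis=0)
    if coords.shape[1] == 1:  # embed chains in the plane
        coords = np.concatenate([coords, np.zeros_like(coords)], axis=1)
    return SpatialNetwork(_ids(coords.shape[0]), coords, edges)


def _block_cells(levels: int, dim: int) -> np.ndarray:
    """(2**(levels-1), dim, 2) lo/hi corners of nested half-cells of [0,1]^dim."""
    n_blocks = 2 ** (levels - 1)
    cells = np.zeros((n_blocks, dim, 2))
    cells[:, :, 1] = 1.0
    for b in range(n_blocks):
        lo = np.zeros(dim)
        hi = np.ones(dim)
        for level in range(levels - 1):
            axis = level % dim
            bit = (b >> (levels - 2 - level)) & 1
            mid = 0.5 * (lo[axis] + hi[axis])
            if bit:
                lo[axis] = mid
            else:
                hi[axis] = mid
        cells[b, :, 0] = lo
        cells[b, :, 1] = hi
    return cells


def make_hierarchical_modular(
    levels: int,
    base_module_size: int,
    level_probabilities,
    seed: int | None = None,
    embedding_dim: int = 3,
    placement: str = "nested",
) -> SpatialNetwork:
    """Nested stochastic-block network with 2**(levels-1) base modules.

    ``level_probabilities`` lists the connection probability by the deepest
    level at which two nodes share a block, from the coarsest level (the whole
    network) to the deepest (within a base module); it must be strictly
    increasing so that deeper submodules are denser.  N equals
    ``base_module_size * 2**(levels-1)``.

    ``placement="nested"`` (default) assigns each base module a recursively
    halved subcell of the unit cube and scatters its nodes uniformly inside,
    so dense modules are also spatially compact; ``placement="uniform"``
    scatters all nodes uniformly in the unit cube, making geometry independent
    of topology.
    """
    probs = np.asarray(level_probabilities, dtype=float)
    if levels < 1 or base_module_size < 1:
        raise ValueError("levels and base_module_size must be >= 1")
    if probs.shape != (levels,):
        raise ValueError("need one probability per level")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if levels > 1 and (np.any(np.diff(probs) < 0) or not probs[-1] > probs[0]):
        raise ValueError(
            "level probabilities must increase from the coarsest level to the "
            "deepest (denser within deeper submodules)"
        )
    if embedding_dim not in (2, 3):
        raise ValueError("embedding_dim must be 2 or 3")
    if placement not in ("nested", "uniform"):
        raise ValueError("placement must be 'nested' or 'uniform'")

    rng = np.random.default_rng(seed)
    n_blocks = 2 ** (levels - 1)
    n = base_module_size * n_blocks
    block = np.arange(n) // base_module_size

    # deepest shared level of two blocks, from the xor of their binary paths
    xor = np.bitwise_xor.outer(block, block)
    bitlen = np.zeros_like(xor)
    nz = xor > 0
    bitlen[nz] = np.floor(np.log2(xor[nz])).astype(np.int64) + 1
    depth = levels - bitlen  # in 1..levels; == levels within a block
    pmat = probs[depth - 1]

    iu, ju = np.triu_indices(n, k=1)
    draw = rng.random(iu.size)
    keep = draw < pmat[iu, ju]
    edges = np.stack([iu[keep], ju[keep]], axis=1)

    if placement == "nested" and levels > 1:
        cells = _block_cells(levels, embedding_dim)
        lo = cells[block, :, 0]
        hi = cells[block, :, 1]
        coords = lo + rng.random((n, embedding_dim)) * (hi - lo)
    else:
        coords = rng.random((n, embedding_dim))
    return SpatialNetwork(_ids(n), coords, edges)


def expected_hierarchical_edges(levels: int, base_module_size: int, level_probabilities) -> float:
    """Closed-form expected edge count of :func:`make_hierarchical_modular`."""
    probs = np.asarray(level_probabilities, dtype=float)
    n_blocks = 2 ** (levels - 1)
    n = base_module_size * n_blocks
    total = n_blocks * base_module_size * (base_module_size - 1) / 2 * probs[-1]
    # pairs whose deepest shared level is l (1-based, l < levels): they share a
    # block of size n / 2**(l-1) but not its two children
    for level in range(1, levels):
        block_size = n // 2 ** (level - 1)
        child = block_size // 2
        pairs_per_block = child * child
        total += 2 ** (level - 1) * pairs_per_block * probs[level - 1]
    return float(total)


def rewire_random(net: SpatialNetwork, seed: int | None = None) -> SpatialNetwork:
    """Uniformly resample the edge set among simple graphs with the same (N, m).

    Node identities and coordinates are untouched (the "pure random" baseline
    keeps the observed physical placement).
    """
    n, m = net.n_nodes, net.n_edges
    total = n * (n - 1) // 2
    if m > total:
        raise NetworkError("more edges than node pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=m, replace=False)
    # decode linear upper-triangle index -> (i, j)
    chosen.sort()
    i = (n - 2 - np.floor(np.sqrt(-8.0 * chosen + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
    j = chosen - i * (2 * n - i - 1) // 2 + i + 1
    return net.replace_edges(np.stack([i, j], axis=1))


def rewire_degree_preserving(
    net: SpatialNetwork,
    swaps_per_edge: float = 15.0,
    seed: int | None = None,
) -> SpatialNetwork:
    """Maslov–Sneppen rewiring preserving the exact degree sequence.

    ``ceil(swaps_per_edge * m)`` *accepted* double-edge swaps are performed
    (rejected proposals do not count); graphs with no valid swap are returned
    unchanged with a warning.
    """
    m = net.n_edges
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire", stacklevel=2)
        return net.replace_edges(net.edges)
    target = int(math.ceil(swaps_per_edge * m))
    seed_int = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    edges, accepted = maslov_rewire(net.edges, net.n_nodes, target, seed_int)
    if accepted == 0:
        warnings.warn(
            "graph admits no valid degree-preserving swap; returned unchanged",
            stacklevel=2,
        )
    elif accepted < target:
        warnings.warn(
            f"only {accepted}/{target} swaps accepted within the attempt budget",
            stacklevel=2,
        )
    return net.replace_edges(edges)


def make_powerlaw_scatter(
    k: float,
    p: float,
    n_points: int = 200,
    noise_sd: float = 0.1,
    seed: int | None = None,
    n_range: tuple[float, float] = (2.0, 2048.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(n, e) pairs from e = k * n**p with multiplicative log-normal noise.

    Block sizes n are log-uniform over ``n_range`` so every decade of the
    scaling regime is equally represented, and
    e_i = k * n_i**p * exp(eps_i) with eps ~ Normal(0, noise_sd**2).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    lo, hi = n_range
    n = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_points))
    eps = rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else np.zeros(n_points)
    e = k * n**p * np.exp(eps)
    return n, e
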