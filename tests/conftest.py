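import numpy as np
import pytest

from netrent import SpatialNetwork
from netrent.synth import make_lattice


@pytest.fixture
def triangle():
    return SpatialNetwork(["a", "b", "c"], [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]], [[0, 1], [1, 2], [0, 2]])


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by a single bridge edge; unique optimal bisection."""
    coords = [[0, 0], [1, 0], [0, 1], [3, 0], [4, 0], [3, 1]]
    edges = [[0, 1], [1, 2], [0, 2], [3, 4], [4, 5], [3, 5], [2, 3]]
    return SpatialNetwork(list("abcdef"), np.array(coords, float), edges)


@pytest.fixture
def two_cliques4():
    """Two 4-cliques joined by one edge (modularity oracle: Q ~ 0.4231)."""
    edges = [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3],
             [4, 5], [4, 6], [4, 7], [5, 6], [5, 7], [6, 7], [3, 4]]
    coords = np.column_stack([np.arange(8.0), np.zeros(8)])
    return SpatialNetwork([str(i) for i in range(8)], coords, edges)


@pytest.fixture
def lattice44():
    return make_lattice([4, 4])


@pytest.fixture
def lattice16():
    return make_lattice([16, 16])


def brute_force_min_bisection(n, edges, tol=0.1):
    """Exhaustive balanced min-cut oracle for n <= 14 nodes."""
    import itertools

    edges = np.asarray(edges)
    b = max(1, int(np.floor(tol * n)))
    best = None
    for size_a in range((n - b + 1) // 2, n // 2 + 1):
        if abs(2 * size_a - n) > b:
            continue
        for combo in itertools.combinations(range(n), size_a):
            side = np.zeros(n, dtype=bool)
            side[list(combo)] = True
            cut = int(np.count_nonzero(side[edges[:, 0]] != side[edges[:, 1]]))
            if best is None or cut < best:
                best = cut
    return best
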