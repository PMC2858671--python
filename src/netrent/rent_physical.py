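"""Physical Rentian scaling: Rent's rule measured in Euclidean space.

Randomly placed, randomly sized axis-aligned boxes are dropped onto the
embedded network; each box yields the number of nodes n it contains and the
number of edges e with exactly one endpoint inside.  A robust log-log
regression over boxes containing fewer than half the nodes (Region I)
estimates the physical Rent exponent p.  The theoretical minimum exponent for
a given topology is p_min = max(p_T, 1 - 1/D_E): embedding cannot beat the
intrinsic dimensionality of the wiring, nor the surface-to-volume scaling of
the Euclidean space itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fitting import RentFit, fit_loglog_irls
from .network import SpatialNetwork

__all__ = ["BoxSample", "sample_boxes", "fit_physical_rent", "min_physical_exponent"]


@dataclass
class BoxSample:
    """Per-box (n, e) counts plus the box geometry that produced them."""

    n: np.ndarray
    e: np.ndarray
    corners: np.ndarray = field(repr=False)
    sides: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def n_boxes(self) -> int:
        return int(self.n.size)


def sample_boxes(
    net: SpatialNetwork,
    n_boxes: int = 5000,
    seed: int | None = None,
    size_range: tuple[float, float] | None = None,
) -> BoxSample:
    """Drop random axis-aligned boxes (squares/cubes) on the embedded network.

    Corners are uniform in the coordinate bounding volume and side lengths
    uniform between the 5th-percentile nearest-neighbour distance and the full
    extent (overridable via ``size_range``); boxes are clipped to the bounding
    volume so they never overhang it.  Containment is half-open
    (lo <= x < hi) so nodes on shared faces are counted once.  Boxes
    containing no node are discarded and resampled.

    All random draws are made in normalised [0, 1) coordinates, so a uniform
    rescaling of the input coordinates leaves the sample — and any fit on it —
    unchanged under the same seed.
    """
    if net.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    coords = net.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo
    if np.all(extent == 0):
        raise ValueError("all nodes coincident: no bounding volume to sample")
    scale = float(extent.max())

    if size_range is None:
        nn = cKDTree(coords).query(coords, k=2)[0][:, 1]
        s_min = float(np.percentile(nn, 5))
        s_max = scale
    else:
        s_min, s_max = size_range
    if s_min <= 0:
        s_min = 1e-6 * scale
    rng = np.random.default_rng(seed)

    edges = net.edges
    ns: list[np.ndarray] = []
    es: list[np.ndarray] = []
    cs: list[np.ndarray] = []
    ss: list[np.ndarray] = []
    have = 0
    for _ in range(200):  # resampling rounds; each draws the full deficit
        need = n_boxes - have
        if need <= 0:
            break
        corner = lo + rng.random((need, coords.shape[1])) * extent
        side = s_min + rng.random(need) * (s_max - s_min)
        box_lo = corner
        box_hi = np.minimum(corner + side[:, None], hi)
        inside = np.ones((need, net.n_nodes), dtype=bool)
        for d in range(coords.shape[1]):
            c = coords[:, d]
            inside &= (c[None, :] >= box_lo[:, d][:, None]) & (c[None, :] < box_hi[:, d][:, None])
        n_in = inside.sum(axis=1)
        keep = n_in > 0
        if not keep.any():
            continue
        inside = inside[keep]
        cross = inside[:, edges[:, 0]] ^ inside[:, edges[:, 1]] if edges.size else np.zeros((inside.shape[0], 0), bool)
        ns.append(n_in[keep])
        es.append(cross.sum(axis=1))
        cs.append(corner[keep])
        ss.append(side[keep])
        have += int(keep.sum())
    if have < n_boxes:
        raise RuntimeError("could not place the requested number of nonempty boxes")
    n = np.concatenate(ns)[:n_boxes]
    e = np.concatenate(es)[:n_boxes]
    return BoxSample(
        n=n.astype(np.int64),
        e=e.astype(np.int64),
        corners=np.concatenate(cs)[:n_boxes],
        sides=np.concatenate(ss)[:n_boxes],
        seed=seed,
    )


def fit_physical_rent(sample: BoxSample, n_nodes: int, min_boxes: int = 50) -> RentFit:
    """Robust IRLS (bisquare) log-log fit of e on n over Region-I boxes.

    Region II boundary effects are avoided by keeping only boxes with
    n < N/2 (strict); boxes with n < 2 or e < 1 carry no scaling information
    and are dropped too.
    """
    mask = (sample.n < n_nodes / 2.0) & (sample.n >= 2) & (sample.e >= 1)
    if int(mask.sum()) < min_boxes:
        raise ValueError(
            f"only {int(mask.sum())} boxes survive the Region-I filter (need "
            f">= {min_boxes}); sample more boxes or use a larger network"
        )
    fit = fit_loglog_irls(sample.n.astype(float), sample.e.astype(float), mask=mask)
    fit.method = "physical (random boxes, " + fit.method + ")"
    return fit


def min_physical_exponent(p_T: float, D_E: int) -> float:
    """Theoretical minimum physical Rent exponent, max(p_T, 1 - 1/D_E).

    The most efficient possible placement of a topology with topological Rent
    exponent p_T in D_E-dimensional space cannot scale below either the
    topology's own exponent or the surface-to-volume exponent 1 - 1/D_E of
    the embedding space (2/3 in 3-D, 1/2 in 2-D).
    """
    if not 0 <= p_T < 1:
        raise ValueError("p_T must lie in [0, 1)")
    if D_E not in (2, 3):
        raise ValueError("D_E must be 2 or 3")
    return max(float(p_T), 1.0 - 1.0 / D_E)
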