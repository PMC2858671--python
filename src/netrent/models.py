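"""Model/Results front-end over the functional estimators.

Each model wraps one estimator family in the familiar build-then-fit shape:
construct from data, call ``fit()``, get a results object carrying estimates,
uncertainties and a ``summary()``.  The underlying functions remain available
for scripted use.
"""

from __future__ import annotations

import numpy as np

from .allometry import AllometricFit, fit_allometric
from .fitting import RentFit
from .network import SpatialNetwork
from .pipeline import AnalysisConfig, AnalysisReport, run_full_analysis
from .rent_physical import fit_physical_rent, sample_boxes
from .rent_topological import fit_topological_rent, recursive_partition

__all__ = ["TopologicalRentModel", "PhysicalRentModel", "AllometricModel", "RentianAnalysis"]


class TopologicalRentModel:
    """Topological Rent exponent via recursive min-cut partitioning."""

    def __init__(
        self,
        net: SpatialNetwork,
        exclude_top: int = 2,
        restarts: int = 10,
        min_partition_size: int = 2,
        balance_tolerance: float = 0.1,
        boundary: str = "global",
    ):
        self.net = net
        self.exclude_top = exclude_top
        self.restarts = restarts
        self.min_partition_size = min_partition_size
        self.balance_tolerance = balance_tolerance
        self.boundary = boundary
        self.levels_ = None

    def fit(self, seed: int | None = None) -> RentFit:
        self.levels_ = recursive_partition(
            self.net,
            min_partition_size=self.min_partition_size,
            balance_tolerance=self.balance_tolerance,
            seed=seed,
            restarts=self.restarts,
            boundary=self.boundary,
        )
        return fit_topological_rent(self.levels_, exclude_top=self.exclude_top)


class PhysicalRentModel:
    """Physical Rent exponent via random Euclidean box sampling."""

    def __init__(self, net: SpatialNetwork, n_boxes: int = 5000):
        self.net = net
        self.n_boxes = n_boxes
        self.sample_ = None

    def fit(self, seed: int | None = None) -> RentFit:
        self.sample_ = sample_boxes(self.net, n_boxes=self.n_boxes, seed=seed)
        return fit_physical_rent(self.sample_, self.net.n_nodes)


class AllometricModel:
    """Cross-species gray/white-matter allometric scaling."""

    def __init__(self, Vg, Vw):
        self.Vg = np.asarray(Vg, dtype=float)
        self.Vw = np.asarray(Vw, dtype=float)

    @classmethod
    def from_dataframe(cls, df, vg_col: str = "Vg", vw_col: str = "Vw") -> "AllometricModel":
        return cls(df[vg_col].to_numpy(), df[vw_col].to_numpy())

    def fit(self) -> AllometricFit:
        return fit_allometric(self.Vg, self.Vw)


class RentianAnalysis:
    """Full observed / randomly-rewired / minimally-rewired analysis."""

    def __init__(self, net: SpatialNetwork, config: AnalysisConfig | None = None):
        self.net = net
        self.config = config or AnalysisConfig()

    def fit(self, seed: int = 0) -> AnalysisReport:
        return run_full_analysis(self.net, self.config, seed=seed)
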