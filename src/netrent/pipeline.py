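"""Full three-panel analysis: observed, randomly rewired, minimally rewired.

``run_full_analysis`` applies the topological Rent estimator, the physical
Rent estimator and the wiring statistics to the observed network, to 10
randomly rewired instantiations (positions fixed) and to the minimally
rewired variant, mirroring the three panels of the connectome summary table.
A master seed deterministically derives per-stage seeds, so reports are
bitwise reproducible and stages can be rerun independently.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .network import SpatialNetwork
from .rent_physical import fit_physical_rent, sample_boxes
from .rent_topological import fit_topological_rent, recursive_partition, topological_dimension
from .synth import rewire_random
from .wiring import rewire_minimal, wiring_report

log = logging.getLogger("netrent")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed and a name."""
    return zlib.crc32(f"{master}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class AnalysisConfig:
    """Declarative knobs for the full analysis (CLI flags mirror these)."""

    n_random: int = 10
    n_boxes: int = 5000
    restarts: int = 10
    exclude_top: int = 2
    min_partition_size: int = 2
    balance_tolerance: float = 0.1
    boundary: str = "global"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class AnalysisReport:
    observed: dict
    random: list[dict]
    random_mean: dict
    minimal: dict
    seeds: dict
    config: dict
    n_nodes: int = 0
    n_edges: int = 0
    density: float = 0.0
    embedding_dim: int = 0
    schema_version: str = "1"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def summary(self):
        """Table-style summary (one row per variant) as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for name, entry in [("observed", self.observed), ("random (mean of %d)" % len(self.random), self.random_mean), ("minimal", self.minimal)]:
            rows.append(
                {
                    "variant": name,
                    "p_T": entry.get("p_T"),
                    "D_T": entry.get("D_T"),
                    "p": entry.get("p"),
                    "L_bar": entry.get("L_bar"),
                    "kappa": entry.get("kappa"),
                    "mean_edge_length": entry.get("mean_edge_length"),
                }
            )
        return pd.DataFrame(rows).set_index("variant")


def _analyze_variant(net: SpatialNetwork, cfg: AnalysisConfig, seed: int, stage: str) -> dict:
    out: dict = {
        "N": net.n_nodes,
        "m": net.n_edges,
        "density": net.density,
        "D_E": net.embedding_dim,
    }
    t0 = time.perf_counter()
    try:
        levels = recursive_partition(
            net,
            min_partition_size=cfg.min_partition_size,
            balance_tolerance=cfg.balance_tolerance,
            seed=stage_seed(seed, stage + ":partition"),
            restarts=cfg.restarts,
            boundary=cfg.boundary,
        )
        tfit = fit_topological_rent(levels, exclude_top=cfg.exclude_top)
        out["p_T"] = tfit.exponent
        out["p_T_ci95"] = list(tfit.ci95)
        if tfit.exponent < 1:
            d, dci = topological_dimension(tfit.exponent, tfit.ci95)
            out["D_T"] = d
            out["D_T_ci95"] = [dci[0] if np.isfinite(dci[0]) else None, dci[1] if np.isfinite(dci[1]) else None]
        else:
            out["D_T"] = None
            out["D_T_ci95"] = None
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}:topological' failed: {exc}") from exc
    log.info("%s: topological fit done in %.2fs", stage, time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        sample = sample_boxes(net, n_boxes=cfg.n_boxes, seed=stage_seed(seed, stage + ":boxes"))
        pfit = fit_physical_rent(sample, net.n_nodes)
        out["p"] = pfit.exponent
        out["p_ci95"] = list(pfit.ci95)
        out["k"] = pfit.coefficient_k
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}:physical' failed: {exc}") from exc
    log.info("%s: physical fit done in %.2fs", stage, time.perf_counter() - t0)

    rep = wiring_report(net, D_T=out.get("D_T"))
    out["delta"] = rep.delta
    out["L_bar"] = rep.L_bar
    out["mean_edge_length"] = rep.mean_edge_length
    out["kappa"] = rep.kappa  # None mirrors the N/A regime D_T <= D_E
    return out


def run_full_analysis(net: SpatialNetwork, config: AnalysisConfig | None = None, seed: int = 0) -> AnalysisReport:
    """Observed + 10x randomly rewired + minimally rewired analysis report."""
    cfg = config or AnalysisConfig()
    seeds = {"master": seed}

    observed = _analyze_variant(net, cfg, seed, "observed")

    randoms: list[dict] = []
    for i in range(cfg.n_random):
        s = stage_seed(seed, f"random:{i}")
        seeds[f"random:{i}"] = s
        variant = rewire_random(net, seed=s)
        randoms.append(_analyze_variant(variant, cfg, seed, f"random:{i}"))

    keys = ("p_T", "D_T", "p", "L_bar", "kappa", "mean_edge_length", "delta")
    random_mean: dict = {}
    for key in keys:
        vals = [r[key] for r in randoms if r.get(key) is not None]
        random_mean[key] = float(np.mean(vals)) if vals else None
        random_mean[key + "_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None

    minimal_net = rewire_minimal(net)
    minimal = _analyze_variant(minimal_net, cfg, seed, "minimal")

    return AnalysisReport(
        observed=observed,
        random=randoms,
        random_mean=random_mean,
        minimal=minimal,
        seeds=seeds,
        config=asdict(cfg),
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=net.density,
        embedding_dim=net.embedding_dim,
    )
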