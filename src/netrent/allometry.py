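"""Allometric gray/white-matter scaling and its link to the Rent exponent.

Across mammalian species, white-matter volume scales with gray-matter volume
as Vw ∝ Vg^a.  Approximating the brain as a sphere, the cross-sectional area
carrying inter-regional connections scales as A ∝ Vw^(2/3); with connection
density per unit area (σ) and processing elements per unit gray volume (ρ)
constant across species, Rent's rule e = k·n^p turns the volumetric exponent
into a = (3/2)·p, i.e. p = (2/3)·a.  The functions here convert between the
two exponents, fit a from (Vg, Vw) data by log-log least squares, and predict
white-matter volumes from a Rent exponent through an anchor species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "allometric_to_rent",
    "rent_to_allometric",
    "fit_allometric",
    "predict_white_matter",
    "AllometricFit",
]


def allometric_to_rent(a: float) -> float:
    """Rent exponent implied by an allometric exponent: p = (2/3) * a."""
    if a <= 0:
        raise ValueError("allometric exponent must be positive")
    return (2.0 / 3.0) * a


def rent_to_allometric(p: float, ci95: tuple[float, float] | None = None):
    """Allometric exponent implied by a Rent exponent: a = (3/2) * p.

    With ``ci95`` given, the interval is propagated linearly and
    ``(a, (lo, hi))`` is returned.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    a = 1.5 * p
    if ci95 is None:
        return a
    return a, (1.5 * ci95[0], 1.5 * ci95[1])


@dataclass
class AllometricFit:
    """OLS fit of log Vw on log Vg."""

    a: float
    ci95: tuple[float, float]
    intercept: float
    stderr: float
    r_squared: float
    n: int

    @property
    def rent_exponent(self) -> float:
        return allometric_to_rent(self.a)

    @property
    def rent_ci95(self) -> tuple[float, float]:
        return (2.0 / 3.0 * self.ci95[0], 2.0 / 3.0 * self.ci95[1])

    def summary(self) -> str:
        return (
            "Allometric scaling fit (log Vw ~ log Vg)\n"
            f"  species            : {self.n}\n"
            f"  exponent a         : {self.a:.4f}  [{self.ci95[0]:.4f}, {self.ci95[1]:.4f}]\n"
            f"  implied Rent p     : {self.rent_exponent:.4f}  "
            f"[{self.rent_ci95[0]:.4f}, {self.rent_ci95[1]:.4f}]\n"
            f"  R^2                : {self.r_squared:.4f}"
        )


def fit_allometric(Vg, Vw) -> AllometricFit:
    """Fit Vw = C * Vg^a by ordinary least squares in log-log space."""
    Vg = np.asarray(Vg, dtype=float)
    Vw = np.asarray(Vw, dtype=float)
    if Vg.size != Vw.size or Vg.size < 2:
        raise ValueError("need at least 2 (Vg, Vw) pairs of equal length")
    if np.any(Vg <= 0) or np.any(Vw <= 0):
        raise ValueError("volumes must be strictly positive")
    x, y = np.log(Vg), np.log(Vw)
    if Vg.size == 2:  # exact line through both points
        a = (y[1] - y[0]) / (x[1] - x[0])
        return AllometricFit(float(a), (float(a), float(a)), float(y[0] - a * x[0]), 0.0, 1.0, 2)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = np.asarray(res.conf_int(alpha=0.05))
    return AllometricFit(
        a=float(res.params[1]),
        ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        r_squared=float(res.rsquared),
        n=int(Vg.size),
    )


def predict_white_matter(Vg, p: float, anchor: tuple[float, float]) -> np.ndarray:
    """White-matter volumes predicted from a Rent exponent through an anchor.

    Vw(Vg) = Vw_anchor * (Vg / Vg_anchor)^((3/2) p); the curve passes exactly
    through the anchor pair.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    vg_a, vw_a = anchor
    if vg_a <= 0 or vw_a <= 0:
        raise ValueError("anchor volumes must be positive")
    Vg = np.asarray(Vg, dtype=float)
    return vw_a * (Vg / vg_a) ** (1.5 * p)
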