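"""Power-law fitting: the RentFit results object and regression back-ends.

Both Rent exponents are slopes of log(e) on log(n); the topological fit is a
weighted least-squares over partition levels (weights = partitions per level),
the physical fit a robust bisquare IRLS over box samples.  The supplementary
model comparison ranks power / exponential / linear / quadratic fits by
small-sample-corrected AIC on the untransformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm


@dataclass
class RentFit:
    """Fitted Rent relationship e = k * n**p.

    Attributes
    ----------
    exponent
        The Rent exponent p (slope in log-log space).
    ci95
        95% confidence interval on the exponent.
    coefficient_k
        The Rent coefficient k (exp of the log-log intercept).
    region_mask
        Which input points entered the fit (Region I).
    """

    exponent: float
    ci95: tuple[float, float]
    coefficient_k: float
    region_mask: np.ndarray = field(repr=False)
    n_points: int = 0
    stderr: float = float("nan")
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    method: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("non-finite exponent")
        if not self.ci95[0] <= self.exponent <= self.ci95[1]:
            raise ValueError("confidence interval does not contain the estimate")
        if self.coefficient_k <= 0:
            raise ValueError("Rent coefficient must be positive")

    @property
    def dimension(self) -> float:
        """Fractal topological dimension D_T = 1 / (1 - p)."""
        from .rent_topological import topological_dimension

        return topological_dimension(self.exponent)

    @property
    def dimension_ci95(self) -> tuple[float, float]:
        from .rent_topological import topological_dimension

        return topological_dimension(self.exponent, self.ci95)[1]

    def summary(self) -> str:
        lines = [
            f"Rent power-law fit ({self.method})",
            f"  points in region I : {self.n_points}",
            f"  exponent p         : {self.exponent:.4f}  "
            f"[{self.ci95[0]:.4f}, {self.ci95[1]:.4f}] (95% CI)",
            f"  coefficient k      : {self.coefficient_k:.4f}",
            f"  R^2 (log-log)      : {self.r_squared:.4f}",
        ]
        if self.exponent < 1:
            lo, hi = self.dimension_ci95
            lines.append(f"  dimension D_T      : {self.dimension:.3f}  [{lo:.3f}, {hi:.3f}]")
        return "\n".join(lines)


def _finalize(res, mask, n_used, method, logx, logy) -> RentFit:
    slope = float(res.params[1])
    intercept = float(res.params[0])
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    fitted = intercept + slope * logx
    resid = logy - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RentFit(
        exponent=slope,
        ci95=(float(ci[1, 0]), float(ci[1, 1])),
        coefficient_k=float(np.exp(intercept)),
        region_mask=mask,
        n_points=int(n_used),
        stderr=float(res.bse[1]),
        r_squared=r2,
        residuals=resid,
        method=method,
    )


def fit_loglog_wls(n, e, weights=None, mask=None, method="weighted least squares") -> RentFit:
    """Weighted linear regression of log(e) on log(n)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if mask is None:
        mask = np.ones(n.shape, dtype=bool)
    mask = mask & (n > 0) & (e > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} usable points; need at least 3 (use a larger network)"
        )
    logx, logy = np.log(n[mask]), np.log(e[mask])
    w = np.ones(logx.size) if weights is None else np.asarray(weights, dtype=float)[mask]
    X = sm.add_constant(logx)
    res = sm.WLS(logy, X, weights=w).fit()
    return _finalize(res, mask, mask.sum(), method, logx, logy)


def fit_loglog_irls(n, e, mask=None) -> RentFit:
    """Robust (iteratively reweighted, bisquare) regression of log(e) on log(n)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if mask is None:
        mask = np.ones(n.shape, dtype=bool)
    mask = mask & (n > 0) & (e > 0)
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} usable points; need at least 3")
    logx, logy = np.log(n[mask]), np.log(e[mask])
    if np.allclose(logy - (np.polyfit(logx, logy, 1) @ np.vstack([logx, np.ones_like(logx)])), 0.0, atol=1e-12):
        # exact power law: RLM's scale estimate degenerates, fall back to OLS
        res = sm.OLS(logy, sm.add_constant(logx)).fit()
        return _finalize(res, mask, mask.sum(), "irls-bisquare (exact)", logx, logy)
    X = sm.add_constant(logx)
    res = sm.RLM(logy, X, M=sm.robust.norms.TukeyBiweight()).fit()
    return _finalize(res, mask, mask.sum(), "irls-bisquare", logx, logy)


# ---------------------------------------------------------------------------
# supplementary model comparison
# ---------------------------------------------------------------------------

def _aicc(rss: float, n: int, k: int, y_scale: float = 1.0) -> float:
    if rss <= max(1e-300, 1e-18 * y_scale):
        return -np.inf
    k = k + 1  # count the error variance
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def compare_scaling_models(x, y) -> list[dict]:
    """Rank power / exponential / linear / quadratic fits of y on x.

    All models are scored by small-sample-corrected AIC computed from
    residuals on the common untransformed scale, so log-transformed fits do
    not get an unfair variance scale.  Returns a list of dicts sorted best
    first; ties (e.g. several exact fits) break toward fewer parameters, then
    a fixed model order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("model comparison requires positive x and y (log transforms)")
    n = x.size
    results = []

    order = {"linear": 0, "power": 1, "exponential": 2, "quadratic": 3}

    y_scale = float(np.sum(y**2))

    def add(name, k_params, predict, params):
        rss = float(np.sum((y - predict) ** 2))
        results.append(
            {
                "model": name,
                "params": params,
                "rss": rss,
                "aicc": _aicc(rss, n, k_params, y_scale),
                "n_params": k_params,
            }
        )

    b1, b0 = np.polyfit(np.log(x), np.log(y), 1)
    add("power", 2, np.exp(b0) * x**b1, {"k": float(np.exp(b0)), "p": float(b1)})

    c1, c0 = np.polyfit(x, np.log(y), 1)
    add("exponential", 2, np.exp(c0) * np.exp(c1 * x), {"a": float(np.exp(c0)), "b": float(c1)})

    d1, d0 = np.polyfit(x, y, 1)
    add("linear", 2, d0 + d1 * x, {"intercept": float(d0), "slope": float(d1)})

    q2, q1, q0 = np.polyfit(x, y, 2)
    add("quadratic", 3, q0 + q1 * x + q2 * x**2, {"c0": float(q0), "c1": float(q1), "c2": float(q2)})

    results.sort(key=lambda r: (r["aicc"], r["n_params"], order[r["model"]]))
    return results
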