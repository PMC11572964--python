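"""Per-scale cooling-efficiency estimation.

Cooling efficiency (CE) at a scale is the absolute value of the OLS slope
from regressing unit mean LST (degC) on unit percent canopy cover, so it
reads as the LST reduction associated with one percentage point of
additional canopy. A positive (warming) slope is unusual but still yields
CE = |slope|; it is flagged with a warning rather than excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import UnitTable
from .errors import EstimationError


@dataclass(frozen=True)
class CEEstimate:
    """CE regression summary for one analytical-unit size."""

    scale_m: float
    ce: float                 # |slope|, degC per % canopy
    slope_sign: str           # "negative" (cooling) or "positive" (warming)
    intercept_c: float
    se_slope: float
    r2: float
    p_slope: float
    n_units: int

    @property
    def slope(self) -> float:
        """Signed regression slope."""
        return -self.ce if self.slope_sign == "negative" else self.ce

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_ce(table: UnitTable, robust: bool = False) -> CEEstimate:
    """Estimate CE at one scale by simple OLS of mean LST on Ptree.

    Parameters
    ----------
    table : UnitTable
        Per-unit (ptree_pct, lst_mean_c) samples at one scale.
    robust : bool
        Use heteroscedasticity-robust (HC3) standard errors and p-values
        instead of the classical OLS ones. The point estimates are
        unchanged. Off by default.
    """
    df = table.data
    x = df["ptree_pct"].to_numpy(dtype=float)
    y = df["lst_mean_c"].to_numpy(dtype=float)
    if len(x) < 3:
        raise EstimationError(
            f"scale {table.scale_m:g} m: need >= 3 units, have {len(x)}"
        )
    if float(np.var(x)) == 0.0:
        raise EstimationError(
            f"scale {table.scale_m:g} m: zero Ptree variance (degenerate design)"
        )
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    se, p = res.stderr, res.pvalue
    if robust:
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
    if slope > 0:
        warnings.warn(
            f"scale {table.scale_m:g} m: positive (warming) slope {slope:.4g}; "
            "CE recorded as its absolute value"
        )
    return CEEstimate(
        scale_m=table.scale_m,
        ce=abs(slope),
        slope_sign="positive" if slope > 0 else "negative",
        intercept_c=float(intercept),
        se_slope=float(se),
        r2=float(res.rvalue**2),
        p_slope=float(p),
        n_units=len(x),
    )


def estimate_all(tables: list[UnitTable], robust: bool = False) -> list[CEEstimate]:
    """Estimate CE at every scale, skipping degenerate scales with a warning.

    Raises :class:`EstimationError` when fewer than 3 scales are usable,
    since the downstream power-law fit then has no support.
    """
    estimates: list[CEEstimate] = []
    for table in tables:
        try:
            estimates.append(estimate_ce(table, robust=robust))
        except EstimationError as exc:
            warnings.warn(f"skipping scale: {exc}")
    estimates.sort(key=lambda e: e.scale_m)
    if len(estimates) < 3:
        raise EstimationError(
            f"only {len(estimates)} usable scales; >= 3 required for the scaling fit"
        )
    return estimates


def estimates_to_frame(estimates: list[CEEstimate]) -> pd.DataFrame:
    """Tabulate estimates (one row per scale) for CSV export."""
    return pd.DataFrame([e.to_dict() for e in estimates])
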