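"""Power-law scaling of cooling efficiency versus analytical-unit size.

The central model is CE(S) = k * S**beta: the cooling efficiency at unit
size S (m) with normalization constant k (degC per % canopy at S = 1) and
dimensionless scaling exponent beta. beta in (0, 1) means CE rises steeply
across neighborhood scales and flattens toward the whole-city scale.

Fitting is OLS of ln CE on ln S by default (closed-form confidence
intervals; k's interval by exponentiating the intercept bounds), with a
direct nonlinear least-squares option. When the power fit's scale term is
insignificant (p > 0.01 by default) a quadratic in S is fitted instead —
the empirically better form on extreme-heat days, when evapotranspiration
saturates.

The statsmodels-style entry point is :class:`CEScalingModel`, whose
``fit()`` returns a :class:`ScalingFit` results object; the module-level
functions expose the same machinery functionally.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .aggregate import ScaleLadder, UnitTable
from .errors import FitError, ValidationError
from .regression import CEEstimate, estimate_all

logger = logging.getLogger(__name__)


@dataclass
class ScalingFit:
    """Results of fitting CE versus unit size.

    For the power form, ``k`` and ``beta`` are the parameters of
    CE = k * S**beta with 95% intervals ``k_ci`` / ``beta_ci``; for the
    quadratic form, ``quad_coeffs`` holds (c0, c1, c2) of
    CE = c0 + c1*S + c2*S**2. ``p_fit`` is the significance of the scale
    term(s): the slope's two-tailed p in log-log space, or the joint F-test
    p of (S, S**2) for the quadratic.
    """

    model_form: str                       # "power" | "quadratic"
    k: float | None
    beta: float | None
    k_ci: tuple[float, float] | None
    beta_ci: tuple[float, float] | None
    quad_coeffs: tuple[float, float, float] | None
    fit_space: str                        # "log-log" | "direct"
    r2_fit: float
    p_fit: float
    n_scales: int
    s_unit: str = "m"
    s_range: tuple[float, float] | None = None
    per_date: list["ScalingFit"] | None = field(default=None, repr=False)
    # internals for mean-response prediction intervals (log-log fits)
    _pred: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.model_form == "power":
            if self.k is None or self.k <= 0:
                raise FitError("power form requires k > 0")
            for ci, est in ((self.k_ci, self.k), (self.beta_ci, self.beta)):
                if ci is not None and not (ci[0] <= est <= ci[1]):
                    raise FitError("confidence interval does not contain the estimate")
        if self.n_scales < 3:
            raise FitError("a scaling fit needs >= 3 scales")

    def predict(self, s: float | np.ndarray) -> float | np.ndarray:
        """Fitted CE at unit size ``s`` (same unit as the fit)."""
        s = np.asarray(s, dtype=float)
        if self.model_form == "power":
            out = self.k * s**self.beta
        else:
            c0, c1, c2 = self.quad_coeffs
            out = c0 + c1 * s + c2 * s**2
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            "Cooling-efficiency scaling fit",
            "=" * 46,
            f"{'Model form:':<22}{self.model_form}",
            f"{'Fit space:':<22}{self.fit_space}",
            f"{'Scales used:':<22}{self.n_scales}",
            f"{'Unit of S:':<22}{self.s_unit}",
        ]
        if self.s_range:
            lines.append(f"{'S range:':<22}{self.s_range[0]:g} - {self.s_range[1]:g}")
        lines.append("-" * 46)
        if self.model_form == "power":
            lines += [
                f"{'k (degC/% at S=1):':<22}{self.k:.4g}"
                f"   95% CI [{self.k_ci[0]:.4g}, {self.k_ci[1]:.4g}]",
                f"{'beta (exponent):':<22}{self.beta:.4g}"
                f"   95% CI [{self.beta_ci[0]:.4g}, {self.beta_ci[1]:.4g}]",
            ]
        else:
            c0, c1, c2 = self.quad_coeffs
            lines.append(f"{'CE = c0+c1*S+c2*S^2:':<22}c0={c0:.4g} c1={c1:.4g} c2={c2:.4g}")
        lines += [
            f"{'R^2 of fit:':<22}{self.r2_fit:.4f}",
            f"{'p (scale term):':<22}{self.p_fit:.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "k": self.k,
            "beta": self.beta,
            "k_ci": list(self.k_ci) if self.k_ci else None,
            "beta_ci": list(self.beta_ci) if self.beta_ci else None,
            "quad_coeffs": list(self.quad_coeffs) if self.quad_coeffs else None,
            "fit_space": self.fit_space,
            "r2_fit": self.r2_fit,
            "p_fit": self.p_fit,
            "n_scales": self.n_scales,
            "s_unit": self.s_unit,
            "s_range": list(self.s_range) if self.s_range else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScalingFit":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("k_ci", "beta_ci", "quad_coeffs", "s_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def _with_pred(self, pred: dict) -> "ScalingFit":
        self._pred = pred
        return self

    def curve_samples(self, n: int = 100) -> np.ndarray:
        """(S, CE) samples of the fitted curve across the fitted range."""
        lo, hi = self.s_range if self.s_range else (1.0, 1000.0)
        s = np.linspace(lo, hi, n)
        return np.column_stack([s, self.predict(s)])


def _extract(estimates: list[CEEstimate]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = np.array([e.scale_m for e in estimates], dtype=float)
    ce = np.array([e.ce for e in estimates], dtype=float)
    se = np.array([e.se_slope for e in estimates], dtype=float)
    order = np.argsort(s)
    return s[order], ce[order], se[order]


def fit_power_law(
    estimates: list[CEEstimate],
    fit_space: str = "log-log",
    s_unit: str = "m",
    weights: str | None = None,
) -> ScalingFit:
    """Fit CE = k * S**beta to per-scale estimates.

    In ``log-log`` space (default), OLS of ln CE on ln S gives beta as the
    slope and k as the exponentiated intercept, with closed-form 95%
    intervals. ``direct`` space runs nonlinear least squares initialized
    from the log-log solution, with asymptotic intervals. Non-positive CE
    values cannot enter the log fit: they are dropped with a warning and,
    when more than half would be lost, the fit falls back to direct space.

    ``weights="inv_se2"`` weights points by 1 / se_slope**2 (off by
    default; the study design treats the per-scale estimates as equally
    informative points on the scaling curve).
    """
    if fit_space not in ("log-log", "direct"):
        raise ValidationError(f"unknown fit_space {fit_space!r}")
    if weights not in (None, "inv_se2"):
        raise ValidationError(f"unknown weights option {weights!r}")
    if len(estimates) < 3:
        raise FitError(f"power-law fit needs >= 3 scales, have {len(estimates)}")
    s, ce, se = _extract(estimates)
    if np.all(ce <= 0):
        raise FitError("all CE values are non-positive; no power law can be fitted")
    if fit_space == "log-log":
        pos = ce > 0
        n_drop = int((~pos).sum())
        if n_drop:
            warnings.warn(f"dropping {n_drop} non-positive CE value(s) from the log-log fit")
        if n_drop > len(ce) / 2:
            warnings.warn("more than half the CE values are non-positive; using direct space")
            return fit_power_law(estimates, fit_space="direct", s_unit=s_unit)
        s_fit, ce_fit, se_fit = s[pos], ce[pos], se[pos]
        if len(s_fit) < 3:
            raise FitError("fewer than 3 positive CE values for the log-log fit")
        x, y = np.log(s_fit), np.log(ce_fit)
        X = sm.add_constant(x)
        if weights == "inv_se2":
            res = sm.WLS(y, X, weights=1.0 / np.maximum(se_fit, 1e-300) ** 2).fit()
        else:
            res = sm.OLS(y, X).fit()
        if res.df_resid < 1 or not np.isfinite(res.bse[1]):
            raise FitError("singular design in the log-log fit")
        ci = res.conf_int(alpha=0.05)
        beta = float(res.params[1])
        k = float(np.exp(res.params[0]))
        xbar = float(np.average(x)) if weights is None else float(
            np.average(x, weights=1.0 / se_fit**2)
        )
        pred = {
            "n": int(res.nobs),
            "xbar": xbar,
            "sxx": float(np.sum((x - np.mean(x)) ** 2)),
            "s2": float(res.mse_resid),
            "df": int(res.df_resid),
        }
        return ScalingFit(
            model_form="power",
            k=k,
            beta=beta,
            k_ci=(float(np.exp(ci[0, 0])), float(np.exp(ci[0, 1]))),
            beta_ci=(float(ci[1, 0]), float(ci[1, 1])),
            quad_coeffs=None,
            fit_space="log-log",
            r2_fit=float(res.rsquared),
            p_fit=float(res.pvalues[1]),
            n_scales=len(s_fit),
            s_unit=s_unit,
            s_range=(float(s_fit.min()), float(s_fit.max())),
        )._with_pred(pred)

    # direct nonlinear least squares, initialized from the log fit when possible
    try:
        init = fit_power_law(
            [e for e in estimates if e.ce > 0], fit_space="log-log", s_unit=s_unit
        )
        p0 = (init.k, init.beta)
    except FitError:
        p0 = (max(float(np.median(ce[ce > 0])) if np.any(ce > 0) else 1.0, 1e-6), 0.1)
    try:
        popt, pcov = optimize.curve_fit(
            lambda ss, kk, bb: kk * ss**bb, s, ce, p0=p0, maxfev=10000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"direct power-law fit failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise FitError("singular design in the direct power-law fit")
    k, beta = float(popt[0]), float(popt[1])
    if k <= 0:
        raise FitError(f"direct fit produced non-positive k = {k:.4g}")
    df = len(s) - 2
    tcrit = stats.t.ppf(0.975, df)
    se_k, se_b = np.sqrt(np.diag(pcov))
    resid = ce - k * s**beta
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ce - ce.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tstat = beta / se_b if se_b > 0 else np.inf
    p_fit = float(2 * stats.t.sf(abs(tstat), df))
    return ScalingFit(
        model_form="power",
        k=k,
        beta=beta,
        k_ci=(k - tcrit * se_k, k + tcrit * se_k),
        beta_ci=(beta - tcrit * se_b, beta + tcrit * se_b),
        quad_coeffs=None,
        fit_space="direct",
        r2_fit=r2,
        p_fit=p_fit,
        n_scales=len(s),
        s_unit=s_unit,
        s_range=(float(s.min()), float(s.max())),
    )._with_pred({"pcov": pcov.tolist(), "df": df})


def fit_quadratic(estimates: list[CEEstimate], s_unit: str = "m") -> ScalingFit:
    """Fit CE = c0 + c1*S + c2*S**2 by OLS.

    ``p_fit`` is the joint F-test p-value of the two scale terms and
    ``r2_fit`` the coefficient of determination — the quantities compared
    against the power form when selecting a model.
    """
    if len(estimates) < 4:
        raise FitError(f"quadratic fit needs >= 4 scales, have {len(estimates)}")
    s, ce, _ = _extract(estimates)
    X = np.column_stack([np.ones_like(s), s, s**2])
    res = sm.OLS(ce, X).fit()
    if res.df_resid < 1 or not np.all(np.isfinite(res.bse)):
        raise FitError("singular design in the quadratic fit")
    return ScalingFit(
        model_form="quadratic",
        k=None,
        beta=None,
        k_ci=None,
        beta_ci=None,
        quad_coeffs=tuple(float(c) for c in res.params),
        fit_space="direct",
        r2_fit=float(res.rsquared),
        p_fit=float(res.f_pvalue),
        n_scales=len(s),
        s_unit=s_unit,
        s_range=(float(s.min()), float(s.max())),
    )._with_pred({"conf_int": res.conf_int(alpha=0.05).tolist()})


def select_model(
    estimates: list[CEEstimate],
    alpha: float = 0.01,
    fit_space: str = "log-log",
    s_unit: str = "m",
) -> ScalingFit:
    """Fit the power law; fall back to the quadratic when it is insignificant.

    The power form is kept when its scale term has p <= ``alpha`` (0.01 by
    default). Otherwise the quadratic is returned — with both diagnostics
    logged, and with a warning if the quadratic cannot be fitted (the
    power fit is then returned despite its insignificance).
    """
    power = fit_power_law(estimates, fit_space=fit_space, s_unit=s_unit)
    if power.p_fit <= alpha:
        logger.info(
            "power law selected: p=%.3g <= alpha=%.3g (R^2=%.3f)",
            power.p_fit, alpha, power.r2_fit,
        )
        return power
    try:
        quad = fit_quadratic(estimates, s_unit=s_unit)
    except FitError as exc:
        warnings.warn(
            f"power fit insignificant (p={power.p_fit:.3g}) but quadratic "
            f"fallback unavailable ({exc}); returning the power fit"
        )
        return power
    logger.info(
        "quadratic fallback selected: power p=%.3g > alpha=%.3g "
        "(power R^2=%.3f, quadratic R^2=%.3f)",
        power.p_fit, alpha, power.r2_fit, quad.r2_fit,
    )
    return quad


def pool_fits(
    per_date_estimates: list[list[CEEstimate]],
    fit_space: str = "log-log",
    s_unit: str = "m",
) -> ScalingFit:
    """Pool CE estimates across dates into one power-law fit.

    The pooled fit regresses the concatenated (ln S, ln CE) points from
    every date; per-date fits are attached on ``per_date`` so the
    across-date dispersion of (k, beta) can be reported alongside.
    """
    if len(per_date_estimates) < 2:
        raise ValidationError("pooling needs >= 2 dates")
    pooled: list[CEEstimate] = [e for date in per_date_estimates for e in date]
    fit = fit_power_law(pooled, fit_space=fit_space, s_unit=s_unit)
    per_date = []
    for i, date in enumerate(per_date_estimates):
        try:
            per_date.append(fit_power_law(date, fit_space=fit_space, s_unit=s_unit))
        except FitError as exc:
            warnings.warn(f"per-date fit {i} failed: {exc}")
    fit.per_date = per_date
    return fit


class CEScalingModel:
    """Scaling model of cooling efficiency versus analytical-unit size.

    Construct from per-scale CE estimates (or build them from unit tables
    or a raster pair via the ``from_*`` constructors), then call
    :meth:`fit` for a :class:`ScalingFit` results object.

    Examples
    --------
    >>> from coolscale.synthetic import TabularSimConfig, simulate_unit_tables
    >>> tables = simulate_unit_tables(TabularSimConfig(seed=1))
    >>> results = CEScalingModel.from_unit_tables(tables).fit()
    >>> print(results.summary())          # doctest: +SKIP
    """

    def __init__(self, estimates: list[CEEstimate], s_unit: str = "m"):
        if len(estimates) < 3:
            raise ValidationError("CEScalingModel needs >= 3 per-scale estimates")
        self.estimates = sorted(estimates, key=lambda e: e.scale_m)
        self.s_unit = s_unit

    @classmethod
    def from_unit_tables(cls, tables: list[UnitTable], robust: bool = False,
                         s_unit: str = "m") -> "CEScalingModel":
        return cls(estimate_all(tables, robust=robust), s_unit=s_unit)

    @classmethod
    def from_raster(cls, pair, ladder: ScaleLadder,
                    min_valid_fraction: float = 0.5) -> "CEScalingModel":
        from .aggregate import aggregate
        from .raster import coarsen_canopy

        pair = coarsen_canopy(pair)
        tables = aggregate(pair, ladder, min_valid_fraction=min_valid_fraction)
        return cls.from_unit_tables(tables)

    @classmethod
    def from_dataframe(cls, df, scale_col: str = "scale_m",
                       ptree_col: str = "ptree_pct",
                       lst_col: str = "lst_mean_c") -> "CEScalingModel":
        """Build from a long per-unit table with one row per (scale, unit)."""
        import pandas as pd

        tables = []
        for scale, grp in df.groupby(scale_col, sort=True):
            data = pd.DataFrame(
                {
                    "unit_id": np.arange(len(grp)),
                    "ptree_pct": grp[ptree_col].to_numpy(dtype=float),
                    "lst_mean_c": grp[lst_col].to_numpy(dtype=float),
                    "n_valid_px": np.ones(len(grp), dtype=int),
                    "valid_fraction": np.ones(len(grp)),
                }
            )
            tables.append(UnitTable(scale_m=float(scale), data=data))
        return cls.from_unit_tables(tables)

    def fit(self, method: str = "select", fit_space: str = "log-log",
            alpha: float = 0.01, weights: str | None = None) -> ScalingFit:
        """Fit the scaling relation.

        method : "power", "quadratic", or "select" (power with the
        p > alpha quadratic fallback, the default).
        """
        if method == "power":
            return fit_power_law(self.estimates, fit_space=fit_space,
                                 s_unit=self.s_unit, weights=weights)
        if method == "quadratic":
            return fit_quadratic(self.estimates, s_unit=self.s_unit)
        if method == "select":
            return select_model(self.estimates, alpha=alpha,
                                fit_space=fit_space, s_unit=self.s_unit)
        raise ValidationError(f"unknown method {method!r}")
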