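"""Whole-city extrapolation and canopy-goal inversion.

Given a fitted power law CE(S) = k * S**beta, the planning questions are:

* How much LST reduction does one extra percent of canopy buy at the
  whole-city scale S_city?  ->  CE_city = k * S_city**beta.
* How much extra canopy is needed for a target reduction dT?
  ->  goal (%) = dT / CE_city, with the interval obtained by inverting the
  CE interval endpoint-wise (exact for this monotone transform, and
  order-reversing: the lower CE bound gives the upper goal bound).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import PredictionError, ValidationError
from .scaling import ScalingFit


@dataclass(frozen=True)
class CityPrediction:
    """Whole-city cooling prediction and the canopy goal it implies."""

    s_city_m: float                 # evaluation scale (m)
    ce_city: float                  # predicted CE (degC per % canopy)
    ce_ci: tuple[float, float]      # 95% interval
    delta_t_target: float           # target LST reduction (degC)
    utc_goal_pct: float             # required canopy increase (%)
    utc_goal_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = {
            "s_city_m": "m",
            "ce_city": "degC per % canopy",
            "ce_ci": "degC per % canopy",
            "delta_t_target": "degC",
            "utc_goal_pct": "% canopy increase",
            "utc_goal_ci": "% canopy increase",
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def predict_ce(fit: ScalingFit, s_city_m: float) -> tuple[float, tuple[float, float]]:
    """Predict CE at the whole-city scale from a power-law fit.

    Returns the point prediction k * S**beta and a 95% interval for the
    mean response: in log-log space this is the classical prediction band
    of the regression line, exponentiated; for direct-space fits it comes
    from the delta method on the parameter covariance.

    A quadratic fit is refused — a concave quadratic extrapolated beyond
    the fitted range turns physically meaningless (decreasing, then
    negative, CE), so the caller must evaluate it explicitly within range.
    """
    if fit.model_form != "power":
        raise PredictionError(
            "whole-city prediction requires a power-law fit; a quadratic fit "
            "must be evaluated explicitly via fit.predict(s) within its range"
        )
    if s_city_m <= 0:
        raise ValidationError("s_city_m must be > 0")
    if fit.s_range and not (fit.s_range[0] <= s_city_m <= fit.s_range[1]):
        warnings.warn(
            f"s_city = {s_city_m:g} lies outside the fitted range "
            f"{fit.s_range}; this is an extrapolation"
        )
    ce = fit.k * s_city_m**fit.beta
    pred = fit._pred or {}
    if fit.fit_space == "log-log" and {"n", "xbar", "sxx", "s2", "df"} <= pred.keys():
        x0 = np.log(s_city_m)
        yhat = np.log(fit.k) + fit.beta * x0
        se = np.sqrt(pred["s2"] * (1.0 / pred["n"] + (x0 - pred["xbar"]) ** 2 / pred["sxx"]))
        t = stats.t.ppf(0.975, pred["df"])
        ci = (float(np.exp(yhat - t * se)), float(np.exp(yhat + t * se)))
    elif "pcov" in pred:
        pcov = np.asarray(pred["pcov"])
        grad = np.array([s_city_m**fit.beta, fit.k * s_city_m**fit.beta * np.log(s_city_m)])
        se = float(np.sqrt(grad @ pcov @ grad))
        t = stats.t.ppf(0.975, pred.get("df", max(fit.n_scales - 2, 1)))
        ci = (ce - t * se, ce + t * se)
    else:
        # fit deserialized without internals: fall back to the parameter CIs
        ci = (fit.k_ci[0] * s_city_m ** fit.beta_ci[0] if s_city_m >= 1
              else fit.k_ci[0] * s_city_m ** fit.beta_ci[1],
              fit.k_ci[1] * s_city_m ** fit.beta_ci[1] if s_city_m >= 1
              else fit.k_ci[1] * s_city_m ** fit.beta_ci[0])
    return float(ce), (float(ci[0]), float(ci[1]))


def utc_goal(
    ce_city: float,
    ce_ci: tuple[float, float],
    delta_t_target: float,
    s_city_m: float = float("nan"),
) -> CityPrediction:
    """Invert a city-scale CE into the canopy increase meeting a target.

    goal (%) = delta_t_target / ce_city; the interval is
    [dT / ce_upper, dT / ce_lower] since goal and CE vary inversely.
    """
    if ce_city <= 0:
        raise ValidationError("ce_city must be > 0")
    if delta_t_target <= 0:
        raise ValidationError("delta_t_target must be > 0")
    lo, hi = float(min(ce_ci)), float(max(ce_ci))
    if lo <= 0:
        raise ValidationError("CE interval must be strictly positive to invert")
    return CityPrediction(
        s_city_m=float(s_city_m),
        ce_city=float(ce_city),
        ce_ci=(lo, hi),
        delta_t_target=float(delta_t_target),
        utc_goal_pct=delta_t_target / ce_city,
        utc_goal_ci=(delta_t_target / hi, delta_t_target / lo),
    )


def predict_city(
    fit: ScalingFit, s_city_m: float, delta_t_target: float
) -> CityPrediction:
    """Convenience: whole-city CE prediction followed by goal inversion."""
    ce, ci = predict_ce(fit, s_city_m)
    return utc_goal(ce, ci, delta_t_target, s_city_m=s_city_m)
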