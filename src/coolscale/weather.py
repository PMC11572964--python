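"""Weather covariates of the scaling exponent.

The scaling exponent beta varies across summer days; relating it to
per-date weather (air temperature, wind speed, relative humidity, vapor
pressure deficit) asks whether hotter or drier days scale faster. Each
covariate is summarized by its Pearson correlation with beta (two-tailed
p via the t transform on n-2 df) together with the OLS slope of beta on
the covariate, since the empirical relationships are close to linear.

VPD is computed from air temperature and relative humidity with the
WMO-standard Magnus approximation when not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import JoinError, ValidationError

#: Magnus saturation-vapor-pressure coefficients (hPa, dimensionless, degC)
MAGNUS_A = 6.112
MAGNUS_B = 17.62
MAGNUS_C = 243.12

WEATHER_COVARIATES = ("air_temp_c", "wind_ms", "rel_humidity_pct", "vpd_hpa")


@dataclass(frozen=True)
class WeatherRecord:
    """Per-date weather conditions for one Landsat acquisition day."""

    date_id: str
    air_temp_c: float
    wind_ms: float
    rel_humidity_pct: float
    vpd_hpa: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rel_humidity_pct <= 100:
            raise ValidationError(
                f"{self.date_id}: relative humidity must be in [0, 100]"
            )
        if self.wind_ms < 0:
            raise ValidationError(f"{self.date_id}: wind speed must be >= 0")


@dataclass(frozen=True)
class ExponentWeatherResult:
    """Association of the scaling exponent with one weather covariate."""

    covariate: str
    r: float              # Pearson correlation
    p_two_tailed: float
    slope: float          # OLS slope of beta on the covariate
    n_dates: int

    def to_dict(self) -> dict:
        return asdict(self)


def saturation_vapor_pressure(air_temp_c):
    """Saturation vapor pressure (hPa) by the Magnus approximation."""
    t = np.asarray(air_temp_c, dtype=float)
    out = MAGNUS_A * np.exp(MAGNUS_B * t / (MAGNUS_C + t))
    return float(out) if out.ndim == 0 else out


def compute_vpd(air_temp_c, rel_humidity_pct):
    """Vapor pressure deficit (hPa) from temperature (degC) and RH (%).

    vpd = es(T) * (1 - RH/100); zero at saturation, equal to es at RH = 0.
    """
    rh = np.asarray(rel_humidity_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValidationError("relative humidity must be in [0, 100]")
    out = saturation_vapor_pressure(air_temp_c) * (1.0 - rh / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def read_weather_csv(path) -> pd.DataFrame:
    """Read per-date weather records, computing VPD where absent.

    Expected columns: date_id, air_temp_c, wind_ms, rel_humidity_pct and
    optionally vpd_hpa.
    """
    df = pd.read_csv(path, dtype={"date_id": str})
    required = {"date_id", "air_temp_c", "wind_ms", "rel_humidity_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"weather table missing columns: {sorted(missing)}")
    if "vpd_hpa" not in df.columns:
        df["vpd_hpa"] = compute_vpd(df["air_temp_c"], df["rel_humidity_pct"])
    else:
        blank = df["vpd_hpa"].isna()
        if blank.any():
            df.loc[blank, "vpd_hpa"] = compute_vpd(
                df.loc[blank, "air_temp_c"], df.loc[blank, "rel_humidity_pct"]
            )
    return df


def correlate_exponents(
    betas: pd.DataFrame | dict, records: pd.DataFrame
) -> list[ExponentWeatherResult]:
    """Correlate per-date scaling exponents with each weather covariate.

    Parameters
    ----------
    betas : DataFrame with columns (date_id, beta), or a {date_id: beta} dict.
    records : weather DataFrame as from :func:`read_weather_csv`.
    """
    if isinstance(betas, dict):
        betas = pd.DataFrame(
            {"date_id": list(betas.keys()), "beta": list(betas.values())}
        )
    betas = betas.copy()
    betas["date_id"] = betas["date_id"].astype(str)
    records = records.copy()
    records["date_id"] = records["date_id"].astype(str)
    missing = sorted(set(betas["date_id"]) - set(records["date_id"]))
    if missing:
        raise JoinError(f"no weather record for date(s): {missing}")
    merged = betas.merge(records, on="date_id", how="inner")
    n = len(merged)
    if n < 3:
        raise ValidationError(f"need >= 3 matched dates, have {n}")
    results = []
    for cov in WEATHER_COVARIATES:
        x = merged[cov].to_numpy(dtype=float)
        y = merged["beta"].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        slope = stats.linregress(x, y).slope
        results.append(
            ExponentWeatherResult(
                covariate=cov, r=float(r), p_two_tailed=float(p),
                slope=float(slope), n_dates=n,
            )
        )
    return results


def results_to_frame(results: list[ExponentWeatherResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
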