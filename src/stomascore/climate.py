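"""Per-location climate trends and sample-pair trend classification.

Monthly series (precipitation in mm, monthly maximum temperature in degrees C)
are reduced to one annual value per location: the hottest month for tmax, and
the annual mean of the seasonal-decomposition trend component for
precipitation. The directionality of change is the sign of an OLS slope of the
annual value over year; significance comes from a two-sided Spearman rank
correlation, Benjamini-Hochberg adjusted across locations within each
variable, at alpha = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.seasonal import seasonal_decompose

logger = logging.getLogger(__name__)

VARIABLES = ("ppt", "tmax")


@dataclass
class ClimateTrend:
    location_id: str
    variable: str
    slope: float
    rho: float
    p_raw: float
    p_adj: float = float("nan")
    direction: str = "none"


def annual_tmax(series: pd.DataFrame) -> pd.DataFrame:
    """One value per year: the month with the highest recorded temperature."""
    out = series.groupby("year", as_index=False)["value"].max()
    return out.rename(columns={"value": "annual"})


def decompose_trend(series: pd.DataFrame, period: int = 12) -> pd.DataFrame:
    """Annualised trend component of a monthly precipitation series.

    Additive decomposition with period 12: the trend is the centred 12-month
    moving average (undefined endpoints dropped), the seasonal component the
    month-wise mean of the detrended series. Trend values are then averaged
    within each year. Requires at least two full periods.
    """
    s = series.sort_values(["year", "month"])
    if len(s) < 2 * period:
        raise ValueError(f"decompose_trend needs >= {2 * period} months, got {len(s)}")
    values = s["value"].to_numpy(dtype=float)
    res = seasonal_decompose(values, model="additive", period=period, two_sided=True)
    trend = res.trend
    out = pd.DataFrame({"year": s["year"].to_numpy(), "trend": trend})
    out = out.dropna()
    annual = out.groupby("year", as_index=False)["trend"].mean()
    return annual.rename(columns={"trend": "annual"})


def trend_test(annual: pd.DataFrame) -> tuple[float, float, float]:
    """OLS slope of value over year plus two-sided Spearman rho and p.

    Returns (slope, rho, p_raw); a constant series yields (0, nan, nan) and is
    later classified as direction 'none'.
    """
    if len(annual) < 3:
        raise ValueError("trend_test requires >= 3 annual values")
    years = annual["year"].to_numpy(dtype=float)
    values = annual["annual"].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return 0.0, float("nan"), float("nan")
    fit = stats.linregress(years, values)
    rho, p = stats.spearmanr(values, years)
    return float(fit.slope), float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    NaN inputs are passed through unadjusted and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def climate_trends(
    long_df: pd.DataFrame, alpha: float = 0.01, period: int = 12, ppt_mode: str = "annual"
) -> pd.DataFrame:
    """Trend table for every (location, variable) in a long monthly table.

    ``long_df`` columns: location_id, variable in {ppt, tmax}, year, month,
    value. BH adjustment is pooled across locations within each variable.
    ``ppt_mode='monthly'`` regresses the monthly trend component directly
    instead of annual aggregates.
    """
    required = {"location_id", "variable", "year", "month", "value"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"climate table missing columns {sorted(missing)}")
    rows = []
    for (loc, var), grp in long_df.groupby(["location_id", "variable"], sort=True):
        if grp.duplicated(["year", "month"]).any():
            raise ValueError(f"duplicate (year, month) records for {loc}/{var}")
        try:
            if var == "tmax":
                annual = annual_tmax(grp)
            elif var == "ppt":
                if ppt_mode == "annual":
                    annual = decompose_trend(grp, period=period)
                else:
                    s = grp.sort_values(["year", "month"])
                    trend = seasonal_decompose(
                        s["value"].to_numpy(float), model="additive", period=period
                    ).trend
                    annual = pd.DataFrame(
                        {"year": np.arange(len(trend), dtype=float), "annual": trend}
                    ).dropna()
            else:
                raise ValueError(f"unknown climate variable {var!r}")
            slope, rho, p_raw = trend_test(annual)
        except ValueError as exc:
            logger.warning("climate_trends: %s/%s skipped (%s)", loc, var, exc)
            slope, rho, p_raw = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "location_id": loc,
                "variable": var,
                "slope": slope,
                "rho": rho,
                "p_raw": p_raw,
            }
        )
    trends = pd.DataFrame(rows)
    trends["p_adj"] = np.nan
    for var in trends["variable"].unique():
        m = trends["variable"] == var
        trends.loc[m, "p_adj"] = bh_adjust(trends.loc[m, "p_raw"].to_numpy())
    sig = trends["p_adj"] < alpha
    trends["direction"] = "none"
    trends.loc[sig & (trends["slope"] > 0), "direction"] = "increase"
    trends.loc[sig & (trends["slope"] < 0), "direction"] = "decrease"
    return trends


def classify_pair(trend_hist: dict | pd.Series, trend_mod: dict | pd.Series) -> str:
    """Classify a sample pair by matching directional climate change.

    'matching_increase'/'matching_decrease' iff both locations show the same
    significant direction; everything else (no change, one-sided change,
    opposing directions) is 'unmatched'. Symmetric in its arguments.
    """
    if trend_hist["variable"] != trend_mod["variable"]:
        raise ValueError(
            f"variable mismatch: {trend_hist['variable']} vs {trend_mod['variable']}"
        )
    dh, dm = trend_hist["direction"], trend_mod["direction"]
    if dh == dm and dh in ("increase", "decrease"):
        return f"matching_{dh}"
    return "unmatched"


def classify_pairs(
    pairs: pd.DataFrame,
    trends: pd.DataFrame,
    sample_to_location: pd.Series,
    variable: str = "ppt",
) -> pd.Series:
    """Vectorised ``classify_pair`` over a kept-pairs table."""
    t = trends[trends["variable"] == variable].set_index("location_id")
    out = []
    for row in pairs.itertuples():
        try:
            th = t.loc[sample_to_location[row.hist_id]]
            tm = t.loc[sample_to_location[row.mod_id]]
        except KeyError:
            out.append("unmatched")
            continue
        out.append(
            classify_pair(
                {"variable": variable, "direction": th["direction"]},
                {"variable": variable, "direction": tm["direction"]},
            )
        )
    return pd.Series(out, index=pairs.index, name=f"climate_class_{variable}")
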