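"""Annual normalized anomalies of the physical driver series.

Raw series arrive at their native cadence (hourly winds, daily lighthouse
SST/SSS and river flow, monthly climate indices, one modelled bloom date per
year).  Each is reduced to seasonal means, normalized against the 1996-2010
base period,

    v_anom[season, year] = (v[season, year] - mean(v[season])) / sd(v[season])

and averaged across the seasons available in each year.  Annual-event
variables (Fraser peak-flow day, spring bloom day) carry one value per year
and are normalized directly at annual cadence.

Wind speed U (m/s) is converted to wind stress with the bulk formula
tau = rho_air * C_D * U^2 (rho_air = 1.22 kg/m^3, C_D = 0.0013) per
observation, before any averaging, since squaring does not commute with the
mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from zooptrends.anomalies import DEFAULT_BASE_PERIOD, _season_columns

logger = logging.getLogger(__name__)

AIR_DENSITY = 1.22  # kg m^-3
DRAG_COEFFICIENT = 0.0013  # dimensionless


def wind_stress(speed) -> np.ndarray | float:
    """Wind stress (N m^-2) from wind speed (m s^-1): 1.22 * 0.0013 * U^2."""
    u = np.asarray(speed, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    tau = AIR_DENSITY * DRAG_COEFFICIENT * u**2
    return float(tau) if np.isscalar(speed) or tau.ndim == 0 else tau


def peak_flow_day(daily_flow: pd.DataFrame, min_days: int = 300) -> pd.Series:
    """Ordinal day of the annual maximum daily flow, per calendar year.

    Ties go to the earliest day.  Years with fewer than ``min_days`` daily
    values are omitted with a warning.

    Parameters
    ----------
    daily_flow : DataFrame with columns ``date`` and ``value``.
    """
    df = daily_flow.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    out = {}
    for year, grp in df.groupby("year"):
        if len(grp) < min_days:
            logger.warning("year %d has only %d daily flow values; omitted", year, len(grp))
            continue
        grp = grp.sort_values("date")
        peak = grp.loc[grp["value"].idxmax(), "date"]
        out[int(year)] = int(peak.dayofyear)
    return pd.Series(out, name="peak_flow_day").sort_index()


def seasonal_means(series: pd.DataFrame) -> pd.DataFrame:
    """Seasonal means of a timestamped series (columns ``date``, ``value``)."""
    sk = _season_columns(series["date"])
    frame = pd.DataFrame(
        {"season": sk["season"].values, "anomaly_year": sk["anomaly_year"].values,
         "value": series["value"].to_numpy(dtype=float)}
    )
    return (
        frame.groupby(["season", "anomaly_year"])["value"].mean().rename("mean").reset_index()
    )


def _normalize(values: pd.Series, base_mask: pd.Series, label: str) -> pd.Series:
    base = values[base_mask]
    sd = base.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"zero base-period variance for {label}")
    return (values - base.mean()) / sd


def normalized_annual_anomaly(
    series: pd.DataFrame,
    base_period=DEFAULT_BASE_PERIOD,
    annual_event: bool = False,
) -> pd.Series:
    """Annual normalized anomaly series (SD units, indexed by year).

    ``annual_event=True`` treats the input as one value per year (columns
    ``year`` and ``value``) and normalizes at annual cadence; otherwise the
    input is a timestamped series reduced to seasonal means first.
    """
    lo, hi = base_period
    if annual_event:
        vals = series.set_index("year")["value"].astype(float).sort_index()
        mask = (vals.index >= lo) & (vals.index <= hi)
        return _normalize(vals, pd.Series(mask, index=vals.index), "annual event").rename("anomaly")
    seas = seasonal_means(series)
    pieces = []
    for season, grp in seas.groupby("season"):
        vals = grp.set_index("anomaly_year")["mean"]
        mask = pd.Series((vals.index >= lo) & (vals.index <= hi), index=vals.index)
        if mask.sum() == 0:
            raise ValueError(f"no base-period values for season {season}")
        pieces.append(_normalize(vals, mask, f"season {season}"))
    anom = pd.concat(pieces, axis=1).mean(axis=1)
    anom.index.name = "year"
    return anom.rename("anomaly").sort_index()
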