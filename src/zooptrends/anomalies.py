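"""Seasonal and annual log10 biomass anomalies from net-tow records.

The anomaly statistic follows the ICES convention for irregularly sampled
plankton series: within each season of each year the arithmetic mean biomass
is computed first and then log10-transformed,

    zbar[s, y] = log10( sum(Z[s, y]) / n[s, y] )

the seasonal climatology is the mean of ``zbar[s, y]`` over the base years
(default 1996-2010), the seasonal anomaly is the departure from that
climatology, and the annual anomaly averages the seasonal anomalies over the
seasons actually sampled.  A one-unit change in the annual anomaly is a
10-fold change in biomass.

True zeros are replaced, per variable, by uniform draws on
(0, min_nonzero / 2) so the log transform is defined; a year counts only if
it has at least one spring or summer observation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "fall")

_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

#: default climatology base period (inclusive)
DEFAULT_BASE_PERIOD = (1996, 2010)

METADATA_COLUMNS = [
    "station_id", "date", "region",
    "bottom_depth_m", "tow_start_depth_m", "day_night",
]


@dataclass(frozen=True)
class SeasonKey:
    """Season label plus the anomaly year it belongs to.

    December is assigned to the winter of the *following* calendar year, so
    Dec 1997 / Jan 1998 / Feb 1998 form one winter (anomaly year 1998).
    """

    season: str
    anomaly_year: int


def assign_season(date) -> SeasonKey:
    """Map a calendar date to its (season, anomaly year)."""
    ts = pd.Timestamp(date)
    season = _MONTH_SEASON[ts.month]
    year = ts.year + 1 if ts.month == 12 else ts.year
    return SeasonKey(season, year)


def _season_columns(dates: pd.Series) -> pd.DataFrame:
    ts = pd.to_datetime(dates)
    month = ts.dt.month
    season = month.map(_MONTH_SEASON)
    year = ts.dt.year + (month == 12).astype(int)
    return pd.DataFrame({"season": season, "anomaly_year": year}, index=dates.index)


def select_tows(records: pd.DataFrame) -> pd.DataFrame:
    """Keep deep-region tows that sample most of the water column.

    A record is retained when its region is central or northern Strait,
    the bottom is deeper than 50 m, and the tow either starts below 150 m or
    (for bottoms shallower than 150 m) covers at least 70% of the column.
    Records with missing depths are rejected with a warning.
    """
    region_ok = records["region"].isin(["central", "northern"])
    bottom = pd.to_numeric(records["bottom_depth_m"], errors="coerce")
    start = pd.to_numeric(records["tow_start_depth_m"], errors="coerce")
    missing = bottom.isna() | start.isna()
    if missing.any():
        logger.warning("rejecting %d records with missing depth fields", missing.sum())
    deep_enough = bottom > 50
    covers = (start > 150) | ((bottom < 150) & (start / bottom >= 0.70))
    keep = region_ok & deep_enough & covers & ~missing
    return records.loc[keep].copy()


def apply_euphausiid_correction(
    records: pd.DataFrame,
    euphausiid_columns=("Euphs",),
    factor: float = 3.0,
) -> pd.DataFrame:
    """Multiply daytime adult-euphausiid biomass/abundance by ``factor``.

    Adult euphausiids see and avoid nets in daylight; the conventional
    correction multiplies daytime catches by 3.  Night tows and all other
    groups are left untouched.
    """
    if "day_night" not in records.columns:
        raise ValueError("records lack a day_night column; correction undefined")
    if records["day_night"].isna().any():
        raise ValueError("day_night flag missing for some records; correction undefined")
    out = records.copy()
    is_day = out["day_night"] == "day"
    for col in euphausiid_columns:
        if col in out.columns:
            out.loc[is_day, col] = out.loc[is_day, col] * factor
    return out


def _variable_rng(master_seed: int, variable: str) -> np.random.Generator:
    # one reproducible stream per variable, stable across processes
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(variable.encode("utf8"))])
    )


def replace_zeros(values, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """Replace true zeros with uniform draws on (0, min_nonzero / 2).

    The minimum non-zero value is taken over the whole collection passed in
    (i.e. all samples of the variable).  Raises if every value is zero.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("biomass values must be non-negative")
    zero = values == 0
    if not zero.any():
        return values.copy()
    nonzero = values[~zero]
    if nonzero.size == 0:
        raise ValueError("all values are zero; zero replacement is undefined")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    half_min = nonzero.min() / 2.0
    out = values.copy()
    draws = rng.uniform(0.0, half_min, size=int(zero.sum()))
    # uniform() can return exactly 0.0; the rule requires strictly positive
    while np.any(draws == 0.0):
        draws[draws == 0.0] = rng.uniform(0.0, half_min, size=int((draws == 0.0).sum()))
    out[zero] = draws
    return out


def seasonal_mean_log10(samples) -> float:
    """log10 of the arithmetic mean biomass (mean first, then log)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample set")
    return float(np.log10(samples.mean()))


def seasonal_stats(
    records: pd.DataFrame,
    value_columns,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Per-(group, season, year) observation counts and mean log10 biomass.

    Zero replacement is applied per variable across all its samples before
    seasonal averaging, with one seeded RNG stream per variable.
    """
    sk = _season_columns(records["date"])
    rows = []
    for col in value_columns:
        vals = records[col].to_numpy(dtype=float)
        if (vals == 0).any():
            vals = replace_zeros(vals, _variable_rng(master_seed, col))
        frame = pd.DataFrame(
            {"season": sk["season"].values, "anomaly_year": sk["anomaly_year"].values,
             "value": vals}
        )
        grouped = frame.groupby(["season", "anomaly_year"])["value"]
        agg = grouped.agg(["count", "mean"]).reset_index()
        agg["mean_log10"] = np.log10(agg["mean"])
        agg["group"] = col
        rows.append(agg[["group", "season", "anomaly_year", "count", "mean_log10"]])
    out = pd.concat(rows, ignore_index=True).rename(columns={"count": "n_obs"})
    return out


def climatology(stats: pd.DataFrame, base_period=DEFAULT_BASE_PERIOD) -> pd.DataFrame:
    """Seasonal climatology: mean of seasonal mean-log10 over base years."""
    lo, hi = base_period
    base = stats[(stats["anomaly_year"] >= lo) & (stats["anomaly_year"] <= hi)]
    clim = (
        base.groupby(["group", "season"])["mean_log10"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "base_mean", "count": "n_years"})
    )
    return clim


def annual_anomalies(stats: pd.DataFrame, clim: pd.DataFrame) -> pd.DataFrame:
    """Annual anomalies per group, applying the spring-or-summer valid-year rule.

    Seasonal anomalies are the seasonal mean-log10 minus the climatological
    seasonal mean; the annual value averages over the seasons observed that
    year.  Years without any spring or summer observation are dropped.
    Raises if a season occurs in the data but has no climatology.
    """
    merged = stats.merge(clim, on=["group", "season"], how="left")
    missing = merged["base_mean"].isna()
    if missing.any():
        bad = merged.loc[missing, ["group", "season"]].drop_duplicates()
        raise ValueError(
            "no climatology for: "
            + "; ".join(f"{g}/{s}" for g, s in bad.itertuples(index=False))
        )
    merged["seasonal_anomaly"] = merged["mean_log10"] - merged["base_mean"]
    valid = (
        merged[merged["season"].isin(["spring", "summer"])]
        .groupby(["group", "anomaly_year"])
        .size()
        .rename("n_spring_summer")
        .reset_index()
    )
    annual = (
        merged.groupby(["group", "anomaly_year"])["seasonal_anomaly"]
        .mean()
        .rename("anomaly")
        .reset_index()
    )
    annual = annual.merge(valid, on=["group", "anomaly_year"], how="inner")
    return annual.drop(columns="n_spring_summer").rename(
        columns={"group": "variable", "anomaly_year": "year"}
    )


def compute_anomalies(
    records: pd.DataFrame,
    value_columns,
    base_period=DEFAULT_BASE_PERIOD,
    master_seed: int = 0,
    select: bool = True,
    euphausiid_columns=("Euphs",),
    correct_euphausiids: bool = True,
) -> pd.DataFrame:
    """Full record-to-anomaly pipeline; returns a wide year x variable table."""
    df = select_tows(records) if select else records
    if correct_euphausiids and any(c in df.columns for c in euphausiid_columns):
        df = apply_euphausiid_correction(df, euphausiid_columns)
    stats = seasonal_stats(df, value_columns, master_seed=master_seed)
    clim = climatology(stats, base_period)
    tidy = annual_anomalies(stats, clim)
    wide = tidy.pivot(index="year", columns="variable", values="anomaly")
    return wide[list(value_columns)]


def screen_collinearity(
    series: pd.DataFrame,
    threshold: float = 0.60,
    min_partners: int = 2,
    min_overlap: int = 3,
):
    """Drop variables highly correlated (|r| > threshold) with several others.

    Pearson correlations are computed on pairwise-complete years.  Variables
    with at least ``min_partners`` high-correlation partners are removed
    greedily by descending partner count (ties broken alphabetically), with
    partner counts recomputed among the survivors after each removal.

    Parameters
    ----------
    series : DataFrame
        Wide table, years as index and one column per annual anomaly series.

    Returns
    -------
    kept, dropped : lists of column names
    corr : DataFrame of pairwise correlations among the input variables
    """
    variances = series.var()
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        raise ValueError(f"zero-variance series: {degenerate}")
    corr = series.corr(min_periods=min_overlap)
    remaining = sorted(series.columns)
    dropped = []
    while True:
        sub = corr.loc[remaining, remaining].abs()
        np.fill_diagonal(sub.values, 0.0)
        degree = (sub > threshold).sum()
        worst = degree[degree >= min_partners]
        if worst.empty:
            break
        # highest degree first; alphabetical tie-break via the sorted index
        victim = worst.sort_index().idxmax()
        dropped.append(victim)
        remaining.remove(victim)
    # perfectly correlated survivors are exact duplicates for any downstream
    # model; keep only the alphabetically first of each such pair
    for a in sorted(remaining):
        if a not in remaining:
            continue
        for b in [c for c in remaining if c > a]:
            if abs(corr.loc[a, b]) >= 1.0 - 1e-12:
                dropped.append(b)
                remaining.remove(b)
    kept = [c for c in series.columns if c in remaining]
    return kept, dropped, corr
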