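"""Synthetic monitoring data with the structure the pipeline assumes.

The generator emulates a multi-decadal zooplankton monitoring program in a
deep temperate strait together with its physical drivers and dependent
salmon survival series:

* two latent annual trends (a U-shaped recovery and a rise-then-decline)
  drive the 12 zooplankton groups through group-specific loadings on the
  log10 biomass scale;
* per-sample biomass is lognormal around the seasonal group mean with true
  zeros injected at a group-specific rate, and sampling effort per season
  and year follows the historical pattern of the program (sparse in the
  early years, dense after 2014);
* physical series are generated at their native cadence (hourly wind, daily
  lighthouse SST/SSS and river flow, monthly climate indices, one bloom date
  per year) as seasonal cycle + loadings on two shared annual axes
  (a temperature/event-timing axis and a salinity axis) + AR(1) noise and
  optional linear trend;
* salmon survival is drawn from a logistic-linear model of chosen annual
  covariates, with the generating coefficients stored for recovery tests.

All randomness flows from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zooptrends.survival import inv_logit

YEARS = tuple(range(1996, 2019))

#: seasonal sample counts of the monitoring program, by year (winter, spring,
#: summer, fall) — sparse early years, dense 2015-2018
DEFAULT_EFFORT = {
    1996: (2, 2, 0, 0), 1997: (1, 2, 4, 4), 1998: (9, 7, 4, 2),
    1999: (0, 2, 5, 0), 2000: (0, 2, 2, 0), 2001: (0, 2, 6, 0),
    2002: (8, 1, 0, 0), 2003: (0, 1, 1, 6), 2004: (2, 14, 3, 8),
    2005: (3, 4, 1, 1), 2006: (0, 5, 0, 4), 2007: (2, 3, 1, 1),
    2008: (2, 4, 11, 13), 2009: (9, 6, 15, 16), 2010: (7, 0, 9, 5),
    2011: (4, 0, 3, 2), 2012: (0, 3, 8, 6), 2013: (0, 13, 7, 7),
    2014: (0, 12, 15, 10), 2015: (3, 65, 42, 27), 2016: (10, 59, 57, 30),
    2017: (14, 37, 31, 12), 2018: (7, 31, 14, 9),
}

SEASON_MONTHS = {"winter": (12, 1, 2), "spring": (3, 4, 5),
                 "summer": (6, 7, 8), "fall": (9, 10, 11)}

#: (trend-1 loading, trend-2 loading, base log10 biomass, zero probability)
DEFAULT_GROUPS = {
    "AmphiHyp": (0.40, -0.20, -0.3, 0.02),
    "CalCops.larg": (0.80, 0.00, 0.5, 0.01),
    "CalCops.med": (0.70, 0.10, 0.6, 0.01),
    "CalCops.smal": (0.30, -0.30, 0.2, 0.01),
    "Chaetognatha": (0.10, 0.70, 0.0, 0.02),
    "Cladocera": (0.30, -0.20, -0.8, 0.10),
    "Ctenophora": (0.00, -0.40, -1.0, 0.15),
    "Euphs": (0.20, 0.20, 0.7, 0.01),
    "Fish": (0.00, -0.60, -0.9, 0.10),
    "Medusae": (0.10, -0.50, -0.5, 0.05),
    "Ostracoda": (0.60, 0.00, -0.7, 0.05),
    "PolychaetPelagic": (0.40, -0.30, -0.6, 0.05),
}

#: physical variables: (axis-1 loading, axis-2 loading, linear trend per year
#: in native units, AR(1) coefficient, sub-annual noise SD, base level,
#: seasonal amplitude, year-level idiosyncratic noise SD).
#: The year-level noise keeps the retained variables below the |r| = 0.60
#: screen with each other, while the redundant basin-scale indices
#: (NPGO/MEI/ONI/SOI) and Sand Heads air temperature shadow the shared axes
#: closely enough to be screened out, as in the monitoring data.
DEFAULT_PHYSICAL = {
    "Entr.SST": (0.60, 0.0, 0.02, 0.6, 0.6, 10.5, 4.5, 0.65),
    "Chrom.SST": (0.60, 0.0, 0.03, 0.6, 0.6, 10.8, 4.5, 0.65),
    "Entr.SSS": (0.0, 0.75, 0.0, 0.5, 0.8, 26.0, 2.0, 0.50),
    "Chrom.SSS": (0.0, 0.60, 0.0, 0.5, 0.8, 27.5, 1.5, 0.65),
    "Nan.vT": (0.60, 0.0, 0.01, 0.7, 0.3, 9.5, 0.8, 0.60),
    "SH.WSpd": (0.15, -0.20, 0.0, 0.3, 2.0, 5.5, 1.5, 0.80),
    "PDO": (0.75, 0.0, 0.0, 0.7, 0.6, 0.0, 0.0, 0.50),
    "NPGO": (-0.70, 0.1, 0.0, 0.7, 0.6, 0.0, 0.0, 0.35),
    "MEI": (0.75, 0.0, 0.0, 0.6, 0.7, 0.0, 0.0, 0.25),
    "ONI": (0.75, 0.0, 0.0, 0.6, 0.7, 0.0, 0.0, 0.25),
    "SOI": (-0.75, 0.0, 0.0, 0.6, 0.7, 0.0, 0.0, 0.25),
    "SH.airT": (0.65, 0.0, 0.02, 0.5, 1.5, 10.0, 7.0, 0.30),
}

#: salmon stocks: intercept, covariate coefficients (relative weights on the
#: standardized-logit scale), target explained-variance fraction of the
#: standardized logit, logit centre, logit scale.  The linear predictor is
#: rescaled so signal variance / total variance hits the target, keeping the
#: relative weights; fits in the observed range for such stocks (adj R^2 ~ 0.4-0.85).
DEFAULT_SURVIVAL = {
    "Cowichan River Chinook": (
        -0.35, {"Entr.SSS": -1.107, "Chrom.SST": 1.579, "TotBiom": 3.368},
        0.85, -4.82, 0.53,
    ),
    "Puntledge River Chinook": (
        -0.01, {"Entr.SSS": 1.123, "CalCops.med": 5.505}, 0.45, -4.97, 0.50,
    ),
    "Harrison River Chinook": (
        0.01, {"FR.flow": 1.629, "SH.WStr": 6.615, "Fish": 0.962, "Chaetognatha": 2.120},
        0.60, -4.02, 0.72,
    ),
    "Big Qualicum River Coho": (
        -0.31, {"TotBiom": 3.251, "CalCops.smal": 1.732}, 0.58, -4.80, 0.89,
    ),
}


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic monitoring-program generator."""

    years: tuple = YEARS
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    effort: dict = field(default_factory=lambda: dict(DEFAULT_EFFORT))
    physical: dict = field(default_factory=lambda: dict(DEFAULT_PHYSICAL))
    survival: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL))
    sample_sigma_log10: float = 0.45  # per-sample lognormal spread
    season_effect: dict = field(
        default_factory=lambda: {"winter": -0.25, "spring": 0.1, "summer": 0.25, "fall": 0.0}
    )
    trend_noise_sd: float = 0.15  # random-walk wiggle on the latent shapes
    master_seed: int = 0


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def latent_trend_shapes(years) -> pd.DataFrame:
    """Deterministic program-era annual shapes, standardized to SD 1.

    zoo1: U-shape with a late-2000s minimum; zoo2: rise to an early-2000s
    peak then decline; phys1: ~decadal sinusoid; phys2: early-2000s dome
    flattening out in the final third of the series.
    """
    y = np.asarray(years, dtype=float)
    zoo1 = _standardize(((y - 2009.0) / 9.0) ** 2)
    zoo2 = _standardize(np.where(y <= 2002, (y - 1996) / 6.0, 1.0 - (y - 2002) / 7.0))
    phys1 = _standardize(np.sin(2 * np.pi * (y - 1994.0) / 10.0))
    phys2 = _standardize(
        np.where(y <= 2001, (y - 1996) / 5.0, np.maximum(1.0 - (y - 2001) / 10.0, 0.0))
    )
    return pd.DataFrame(
        {"zoo1": zoo1, "zoo2": zoo2, "phys1": phys1, "phys2": phys2},
        index=np.asarray(years, dtype=int),
    )


def latent_trends(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Shapes plus seeded random-walk wiggle (the realized true trends)."""
    shapes = latent_trend_shapes(spec.years)
    walk = np.cumsum(
        rng.normal(0.0, spec.trend_noise_sd, size=shapes.shape), axis=0
    )
    return shapes + (walk - walk.mean(axis=0))


def generate_zooplankton_samples(spec: GeneratorSpec, seed: int | None = None):
    """Sample records table plus the generating truth.

    Returns (records, truth) where ``records`` has the schema the anomaly
    engine consumes (station_id, date, region, depths, day_night, one biomass
    column per group) and ``truth`` holds the realized trends, loadings and
    the implied true annual log10 anomalies per group.
    """
    master = spec.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 1]))
    trends = latent_trends(spec, rng)
    rows = []
    for year in spec.years:
        counts = spec.effort.get(year, (0, 0, 0, 0))
        for season, n in zip(("winter", "spring", "summer", "fall"), counts):
            months = SEASON_MONTHS[season]
            for _ in range(int(n)):
                month = int(rng.choice(months))
                cal_year = year - 1 if month == 12 else year
                day = int(rng.integers(1, 28))
                bottom = float(rng.uniform(165, 405))  # start depth stays > 150 m
                start = bottom - 10.0
                record = {
                    "station_id": f"S{rng.integers(1, 18):02d}",
                    "date": f"{cal_year:04d}-{month:02d}-{day:02d}",
                    "region": rng.choice(["central", "northern"], p=[0.7, 0.3]),
                    "bottom_depth_m": round(bottom, 1),
                    "tow_start_depth_m": round(start, 1),
                    "day_night": rng.choice(["day", "night"], p=[0.6, 0.4]),
                }
                for group, (l1, l2, base, p_zero) in spec.groups.items():
                    mean_log10 = (
                        base
                        + spec.season_effect[season]
                        + l1 * trends.loc[year, "zoo1"]
                        + l2 * trends.loc[year, "zoo2"]
                    )
                    if rng.uniform() < p_zero:
                        biomass = 0.0
                    else:
                        biomass = 10.0 ** (
                            mean_log10 + rng.normal(0.0, spec.sample_sigma_log10)
                        )
                    record[group] = biomass
                rows.append(record)
    records = pd.DataFrame(rows)
    loadings = pd.DataFrame(
        {g: (v[0], v[1]) for g, v in spec.groups.items()}, index=["zoo1", "zoo2"]
    ).T
    truth = {"trends": trends, "loadings": loadings}
    return records, truth


def _ar1(n: int, phi: float, sd: float, rng) -> np.ndarray:
    x = np.zeros(n)
    innov_sd = sd * np.sqrt(max(1 - phi**2, 1e-6))
    e = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    x[0] = rng.normal(0.0, sd)
    return x


def generate_physical_series(spec: GeneratorSpec, seed: int | None = None):
    """Physical driver tables at native cadence plus the generating truth.

    Returns (series, truth): ``series`` maps variable name to a DataFrame
    with ``date``/``value`` columns (hourly wind speed, daily SST/SSS and
    flow, monthly climate indices) plus ``BloomDay`` as a ``year``/``value``
    table; Fraser peak-flow day is implied by the daily flow curve.
    """
    master = spec.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 2]))
    trends = latent_trends(spec, rng)
    years = np.asarray(spec.years, dtype=int)
    y0 = years[0]
    series = {}
    for name, (a1, a2, lin, phi, sd, base, amp, annual_sd) in spec.physical.items():
        annual = (
            a1 * trends["phys1"].to_numpy()
            + a2 * trends["phys2"].to_numpy()
            + lin * (years - y0)
            + rng.normal(0.0, annual_sd, size=len(years))
        )
        if name == "SH.WSpd":
            idx = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31 23:00", freq="h")
        elif name in {"PDO", "NPGO", "MEI", "ONI", "SOI"}:
            idx = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS")
        else:
            idx = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
        doy = idx.dayofyear.to_numpy()
        seasonal = amp * np.sin(2 * np.pi * (doy - 105) / 365.25)
        annual_at = annual[np.clip(idx.year.to_numpy() - y0, 0, len(years) - 1)]
        noise = _ar1(len(idx), phi, sd, rng)
        vals = base + seasonal + annual_at + noise
        if name == "SH.WSpd":
            vals = np.abs(vals)
        series[name] = pd.DataFrame({"date": idx, "value": vals})

    # daily Fraser flow: snowmelt peak whose timing follows (negatively) the
    # temperature/event-timing axis, amplitude following (negatively) axis 2
    idx = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = idx.dayofyear.to_numpy()
    yr = idx.year.to_numpy()
    peak_day = (
        166
        - 8 * trends["phys1"].to_numpy()
        - 0.3 * (years - y0)
        + rng.normal(0, 8, size=len(years))
    )
    amp_flow = 7000 * (1 - 0.25 * trends["phys2"].to_numpy())
    pk = peak_day[np.clip(yr - y0, 0, len(years) - 1)]
    am = amp_flow[np.clip(yr - y0, 0, len(years) - 1)]
    base_flow = 1500 + am * np.exp(-0.5 * ((doy - pk) / 30.0) ** 2)
    flow = base_flow * np.exp(_ar1(len(idx), 0.8, 0.08, rng))
    series["FR.flow"] = pd.DataFrame({"date": idx, "value": flow})

    bloom = np.round(
        90 - 6 * trends["phys1"].to_numpy() + rng.normal(0, 7, size=len(years))
    )
    series["BloomDay"] = pd.DataFrame({"year": years, "value": bloom})
    return series, {"trends": trends, "peak_day": pd.Series(peak_day, index=years)}


def generate_survival(
    spec: GeneratorSpec,
    covariates: pd.DataFrame,
    seed: int | None = None,
    final_through: int = 2014,
    coho_final_through: int = 2016,
):
    """Survival proportions from a logistic-linear model of annual covariates.

    ``covariates`` is a wide year x variable anomaly table containing every
    name used in the spec's survival coefficient maps.  Returns
    (table, truth) where the table has stock / ocean_entry_year / survival /
    status rows and ``truth`` stores the generating coefficients and the
    noiseless linear predictor.
    """
    master = spec.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 3]))
    rows = []
    truth = {}
    for stock, (b0, coefs, target_r2, centre, scale) in spec.survival.items():
        missing = [c for c in coefs if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariates missing for {stock}: {missing}")
        lin = pd.Series(0.0, index=covariates.index, dtype=float)
        for name, c in coefs.items():
            lin = lin + c * covariates[name]
        # rescale the signal so it explains target_r2 of unit total variance
        sig_sd = float(lin.std(ddof=1))
        gain = np.sqrt(target_r2) / sig_sd if sig_sd > 0 else 0.0
        resid_sd = float(np.sqrt(1.0 - target_r2))
        lin = b0 + (lin - float(lin.mean())) * gain
        coefs = {name: c * gain for name, c in coefs.items()}
        alpha = lin + rng.normal(0.0, resid_sd, size=len(lin))
        surv = inv_logit(alpha.to_numpy() * scale + centre)
        cutoff = coho_final_through if "Coho" in stock else final_through
        for year, s in zip(covariates.index, surv):
            if np.isnan(s):
                continue
            rows.append(
                {
                    "stock": stock,
                    "ocean_entry_year": int(year),
                    "survival": float(s),
                    "status": "final" if year <= cutoff else "preliminary",
                }
            )
        truth[stock] = {"intercept": b0, "coefficients": dict(coefs),
                        "target_r2": target_r2, "resid_sd": resid_sd,
                        "centre": centre, "scale": scale, "linear_predictor": lin}
    return pd.DataFrame(rows), truth
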