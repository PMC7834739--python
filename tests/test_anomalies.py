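"""Anomaly engine: seasons, tow selection, zero handling, anomalies, screening."""

import numpy as np
import pandas as pd
import pytest

from zooptrends import anomalies as an


@pytest.mark.parametrize(
    "date,season,year",
    [
        ("1997-12-15", "winter", 1998),  # December belongs to next year's winter
        ("1996-03-01", "spring", 1996),
        ("2018-11-30", "fall", 2018),
        ("2000-01-31", "winter", 2000),
        ("2005-07-04", "summer", 2005),
    ],
)
def test_assign_season(date, season, year):
    key = an.assign_season(date)
    assert (key.season, key.anomaly_year) == (season, year)


def _record_frame(rows):
    base = {
        "station_id": "S01", "date": "2000-04-01", "region": "central",
        "bottom_depth_m": 290.0, "tow_start_depth_m": 250.0, "day_night": "day",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def test_select_tows_rules():
    df = _record_frame(
        [
            {"bottom_depth_m": 290, "tow_start_depth_m": 250},       # deep, kept
            {"bottom_depth_m": 120, "tow_start_depth_m": 90},        # 0.75 >= 0.70
            {"bottom_depth_m": 300, "tow_start_depth_m": 100},       # fails both
            {"region": "other", "bottom_depth_m": 290, "tow_start_depth_m": 250},
            {"bottom_depth_m": 45, "tow_start_depth_m": 40},         # too shallow
            {"bottom_depth_m": np.nan, "tow_start_depth_m": 200},    # missing depth
        ]
    )
    kept = an.select_tows(df)
    assert list(kept.index) == [0, 1]


def test_euphausiid_daytime_correction():
    df = _record_frame(
        [
            {"day_night": "day", "Euphs": 2.0, "CalCops.med": 1.5},
            {"day_night": "night", "Euphs": 2.0, "CalCops.med": 1.5},
        ]
    )
    out = an.apply_euphausiid_correction(df)
    assert out.loc[0, "Euphs"] == pytest.approx(6.0)
    assert out.loc[1, "Euphs"] == pytest.approx(2.0)
    assert (out["CalCops.med"] == 1.5).all()  # other groups untouched
    with pytest.raises(ValueError):
        an.apply_euphausiid_correction(df.drop(columns="day_night"))


def test_replace_zeros_bounds_and_determinism():
    vals = [0.0, 4.0, 8.0]
    out1 = an.replace_zeros(vals, rng_seed=1)
    out2 = an.replace_zeros(vals, rng_seed=1)
    assert np.array_equal(out1, out2)
    assert 0 < out1[0] < 2.0  # strictly inside (0, min_nonzero / 2)
    assert out1[1] == 4.0 and out1[2] == 8.0
    assert np.array_equal(an.replace_zeros([1.0, 2.0, 3.0]), [1, 2, 3])
    with pytest.raises(ValueError):
        an.replace_zeros([0.0, 0.0, 0.0])


@pytest.mark.parametrize(
    "samples,expected",
    [([10, 100], np.log10(55)), ([1], 0.0), ([0.1, 0.1, 0.1], -1.0)],
)
def test_seasonal_mean_is_mean_then_log(samples, expected):
    assert an.seasonal_mean_log10(samples) == pytest.approx(expected, abs=1e-10)


def _stats(rows):
    return pd.DataFrame(rows, columns=["group", "season", "anomaly_year", "n_obs", "mean_log10"])


def test_annual_anomaly_averages_only_observed_seasons():
    stats = _stats(
        [
            ("g", "spring", 2000, 3, 0.7),
            ("g", "summer", 2000, 2, 0.3),
            ("g", "summer", 2001, 1, 0.35),
            ("g", "winter", 2002, 2, 0.9),  # no spring/summer: dropped
            ("g", "fall", 2002, 1, 0.6),
        ]
    )
    clim = pd.DataFrame(
        {
            "group": ["g"] * 4,
            "season": ["winter", "spring", "summer", "fall"],
            "base_mean": [0.6, 0.5, 0.5, 0.5],
            "n_years": [5] * 4,
        }
    )
    out = an.annual_anomalies(stats, clim).set_index("year")["anomaly"]
    assert out.loc[2000] == pytest.approx((0.2 + (-0.2)) / 2)
    assert out.loc[2001] == pytest.approx(-0.15)
    assert 2002 not in out.index  # valid-year rule


def test_annual_anomaly_missing_climatology_names_season():
    stats = _stats([("g", "spring", 2000, 1, 0.5)])
    clim = pd.DataFrame(
        {"group": ["g"], "season": ["summer"], "base_mean": [0.5], "n_years": [3]}
    )
    with pytest.raises(ValueError, match="spring"):
        an.annual_anomalies(stats, clim)


def _simple_records(biomass_by_year, month=5):
    rows = []
    for year, values in biomass_by_year.items():
        for v in values:
            rows.append(
                {
                    "station_id": "S01", "date": f"{year}-{month:02d}-10",
                    "region": "central", "bottom_depth_m": 300.0,
                    "tow_start_depth_m": 290.0, "day_night": "night", "g": v,
                }
            )
    return pd.DataFrame(rows)


def test_climatology_years_average_to_zero():
    rng = np.random.default_rng(0)
    data = {y: rng.lognormal(0, 1, size=5) for y in range(1996, 2019)}
    wide = an.compute_anomalies(_simple_records(data), ["g"])
    base = wide.loc[1996:2010, "g"]
    assert base.mean() == pytest.approx(0.0, abs=1e-12)


def test_tenfold_biomass_scaling_shifts_anomaly_by_one():
    rng = np.random.default_rng(1)
    data = {y: rng.lognormal(0, 1, size=4) for y in range(1996, 2019)}
    wide = an.compute_anomalies(_simple_records(data), ["g"])
    data_scaled = dict(data)
    data_scaled[2015] = data[2015] * 10.0
    wide10 = an.compute_anomalies(_simple_records(data_scaled), ["g"])
    assert wide10.loc[2015, "g"] - wide.loc[2015, "g"] == pytest.approx(1.0, abs=1e-12)


def test_sample_order_invariance():
    rng = np.random.default_rng(2)
    data = {y: rng.lognormal(0, 1, size=6) for y in range(1996, 2019)}
    wide = an.compute_anomalies(_simple_records(data), ["g"])
    records = _simple_records(data).sample(frac=1.0, random_state=3).reset_index(drop=True)
    wide_shuffled = an.compute_anomalies(records, ["g"])
    pd.testing.assert_frame_equal(wide, wide_shuffled)


def test_screening_drops_multiply_connected_variable():
    # one variable highly correlated with six others is dropped; a variable
    # with a single high-correlation partner is retained
    rng = np.random.default_rng(4)
    years = np.arange(1996, 2019)
    hub = rng.normal(size=len(years))
    frame = {"hub": hub}
    for i in range(6):
        frame[f"sat{i}"] = hub + rng.normal(0, 0.45, len(years))
    lonely = rng.normal(size=len(years))
    frame["pair_a"] = lonely
    frame["pair_b"] = lonely + rng.normal(0, 0.45, len(years))
    wide = pd.DataFrame(frame, index=years)
    kept, dropped, corr = an.screen_collinearity(wide)
    assert "hub" in dropped
    assert "pair_a" in kept and "pair_b" in kept


def test_screening_independent_series_kept_identical_dropped():
    rng = np.random.default_rng(5)
    years = np.arange(1996, 2019)
    a = rng.normal(size=len(years))
    b = rng.normal(size=len(years))
    kept, dropped, _ = an.screen_collinearity(pd.DataFrame({"a": a, "b": b}, index=years))
    assert dropped == [] and set(kept) == {"a", "b"}
    triple = pd.DataFrame({"x": a, "y": a.copy(), "z": a.copy()}, index=years)
    kept, dropped, _ = an.screen_collinearity(triple)
    assert len(kept) == 1 and len(dropped) == 2
    with pytest.raises(ValueError):
        an.screen_collinearity(pd.DataFrame({"c": np.ones(23), "d": a}, index=years))


def test_climatology_recovers_known_seasonal_means(spec):
    # parameter recovery: with heavy per-season sampling the climatology
    # converges on the generating seasonal mean
    rng = np.random.default_rng(6)
    true_mean = 0.4  # log10 scale
    rows = {y: 10 ** (true_mean + rng.normal(0, 0.2, size=200)) for y in range(1996, 2011)}
    records = _simple_records(rows)
    stats = an.seasonal_stats(records, ["g"])
    clim = an.climatology(stats)
    est = clim.loc[(clim.group == "g") & (clim.season == "spring"), "base_mean"].iloc[0]
    # mean-then-log of a lognormal includes the variance offset
    expected = true_mean + 0.2**2 * np.log(10) / 2
    assert est == pytest.approx(expected, abs=0.02)
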