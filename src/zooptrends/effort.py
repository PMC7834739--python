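"""Resampling experiment on sampling effort.

Could an uneven number of samples per year, rather than the plankton, have
produced the observed anomaly pattern?  The experiment subsamples each
year's pool of tow records down to a fixed effort (historically ~12 samples
per year in the sparse era), recomputes the full anomaly pipeline on every
subsample, and asks how the annual anomalies — and the probability of long
runs of strongly negative anomalies — behave across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zooptrends.anomalies import DEFAULT_BASE_PERIOD, _season_columns, compute_anomalies

#: seasonal distribution of effort in the dense 2015-2018 era (winter,
#: spring, summer, fall sample totals) — the stratification target
DENSE_ERA_SEASON_PROFILE = {"winter": 34, "spring": 192, "summer": 144, "fall": 78}


@dataclass
class EffortScenario:
    """Configuration of one subsampling experiment."""

    n_subsample: int = 12
    n_reps: int = 1000
    threshold: float = -0.10
    run_length: int = 5
    rng_seed: int = 0
    season_profile: dict = field(
        default_factory=lambda: dict(DENSE_ERA_SEASON_PROFILE)
    )


def _allocate(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n draws across strata."""
    raw = n * proportions
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for i in np.argsort(remainder)[::-1][:short]:
        counts[i] += 1
    return counts


def stratified_subsample(
    year_records: pd.DataFrame,
    n: int,
    season_profile: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw n records without replacement, stratified by season.

    Target counts follow ``season_profile`` proportions; strata short of
    their target contribute everything they have and the deficit is filled
    from the remaining records at random.  ``n`` at least the pool size
    returns the full pool (census).
    """
    if n >= len(year_records):
        return year_records
    seasons = _season_columns(year_records["date"])["season"]
    names = list(season_profile)
    props = np.asarray([season_profile[s] for s in names], dtype=float)
    props = props / props.sum()
    targets = _allocate(n, props)
    chosen = []
    for season, target in zip(names, targets):
        idx = year_records.index[seasons == season]
        take = min(target, len(idx))
        if take:
            chosen.extend(rng.choice(idx, size=take, replace=False))
    deficit = n - len(chosen)
    if deficit > 0:
        remaining = year_records.index.difference(chosen)
        chosen.extend(rng.choice(remaining, size=deficit, replace=False))
    return year_records.loc[sorted(chosen)]


def subsampled_anomaly_distribution(
    records: pd.DataFrame,
    variable: str,
    scenario: EffortScenario,
    base_period=DEFAULT_BASE_PERIOD,
) -> dict:
    """Distribution of annual anomalies under reduced, re-stratified effort.

    Each repetition subsamples every year's records to ``n_subsample`` tows
    (stratified by season), recomputes the anomaly pipeline for ``variable``,
    and records the annual anomalies.  Returns a dict with the reps x years
    ``draws`` table and a per-year ``summary`` (mean and quantiles).
    """
    rng = np.random.default_rng(scenario.rng_seed)
    sk = _season_columns(records["date"])
    years = np.sort(sk["anomaly_year"].unique())
    sizes = sk["anomaly_year"].value_counts()
    too_small = sizes[sizes < scenario.n_subsample]
    if len(too_small):
        raise ValueError(
            f"pool smaller than n_subsample in years: {sorted(too_small.index)}"
        )
    draws = []
    for _ in range(scenario.n_reps):
        parts = [
            stratified_subsample(grp, scenario.n_subsample, scenario.season_profile, rng)
            for _, grp in records.groupby(sk["anomaly_year"].values)
        ]
        sub = pd.concat(parts)
        wide = compute_anomalies(
            sub, [variable], base_period=base_period,
            master_seed=scenario.rng_seed, select=False, correct_euphausiids=False,
        )
        draws.append(wide[variable].reindex(years))
    draws = pd.DataFrame(draws, index=pd.RangeIndex(scenario.n_reps, name="rep"))
    summary = pd.DataFrame(
        {
            "mean": draws.mean(),
            "q025": draws.quantile(0.025),
            "q50": draws.quantile(0.50),
            "q975": draws.quantile(0.975),
        }
    )
    return {"draws": draws, "summary": summary}


def run_probability(draws, threshold: float, run_length: int) -> float:
    """Fraction of repetitions with >= run_length consecutive years below threshold."""
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    reps, years = arr.shape
    if run_length > years:
        raise ValueError("run_length exceeds the number of years")
    below = arr < threshold
    hits = 0
    for row in below:
        run = best = 0
        for b in row:
            run = run + 1 if b else 0
            best = max(best, run)
        if best >= run_length:
            hits += 1
    return hits / reps
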