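"""Configuration, readers/writers and the end-to-end pipeline run.

The stages compose in the order of the underlying analysis: tow records to
annual anomalies, physical series to normalized anomalies, collinearity
screening, dynamic factor analysis of both blocks, chronological clustering
of the four latent trends, and regression of responses (latent trends,
total biomass, scaled-logit salmon survival) on the candidate covariates,
with repeated cross-validation and interval predictions.

All inputs are plain CSV; a run writes tidy CSV artifacts plus a manifest
(seeds, config echo) so a rerun with the same seeds is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from zooptrends import anomalies as _an
from zooptrends import synthetic as _syn
from zooptrends.clustering import ConstrainedClustering
from zooptrends.dfa import dfa_model_search, model_table
from zooptrends.effort import EffortScenario, run_probability, subsampled_anomaly_distribution
from zooptrends.physical import normalized_annual_anomaly, peak_flow_day, wind_stress
from zooptrends.regression import ArimaRegressionSearch
from zooptrends.survival import centre_scale

logger = logging.getLogger(__name__)

ANNUAL_EVENT_VARIABLES = {"FR.pkDay", "BloomDay"}


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds of one pipeline run.

    Defaults are the monitoring-analysis conventions: 1996-2010 climatology,
    50 m / 150 m / 70% tow selection, x3 daytime euphausiid factor, 0.60
    collinearity screen, 0.05 KPSS level, at most 5 covariates, 5x5 CV.
    """

    records_csv: str = ""
    physical_dir: str = ""
    survival_csv: str = ""
    out_dir: str = "out"
    climatology: tuple = (1996, 2010)
    min_bottom_depth_m: float = 50.0
    min_tow_start_m: float = 150.0
    min_column_fraction: float = 0.70
    euphausiid_factor: float = 3.0
    collinearity_threshold: float = 0.60
    kpss_alpha: float = 0.05
    max_covariates: int = 5
    cv_repeats: int = 5
    cv_folds: int = 5
    dfa_max_iter: int = 2000
    dfa_em_tol: float = 1e-6
    cluster_n_random: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.climatology = tuple(cfg.climatology)
        return cfg


def write_synthetic_inputs(out_dir, seed: int = 0, spec: _syn.GeneratorSpec | None = None):
    """Generate a complete synthetic input set (records, physical, survival).

    Returns the truth bundle so tests can check recovery.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or _syn.GeneratorSpec(master_seed=seed)
    records, zoo_truth = _syn.generate_zooplankton_samples(spec, seed=seed)
    records.to_csv(out / "zooplankton_records.csv", index=False)
    phys_dir = out / "physical"
    phys_dir.mkdir(exist_ok=True)
    series, phys_truth = _syn.generate_physical_series(spec, seed=seed)
    for name, frame in series.items():
        frame.to_csv(phys_dir / f"{name}.csv", index=False)
    groups = list(spec.groups)
    anoms = _an.compute_anomalies(records, groups, master_seed=seed)
    records["TotBiom"] = records[groups].sum(axis=1)
    tot = _an.compute_anomalies(records, ["TotBiom"], master_seed=seed)
    covariates = pd.concat([anoms, tot], axis=1)
    covariates = pd.concat([covariates, physical_anomalies(phys_dir)], axis=1)
    survival, surv_truth = _syn.generate_survival(spec, covariates, seed=seed)
    survival.to_csv(out / "survival.csv", index=False)
    return {"zooplankton": zoo_truth, "physical": phys_truth, "survival": surv_truth,
            "spec": spec}


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(_an.METADATA_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    return df


def physical_anomalies(
    physical_dir, base_period=(1996, 2010), year_range=(1996, 2018)
) -> pd.DataFrame:
    """Annual normalized anomalies for every physical CSV in a directory.

    ``SH.WSpd`` is converted per-observation to wind stress (``SH.WStr``)
    before averaging; ``FR.flow`` additionally yields the annual peak-flow
    day (``FR.pkDay``); ``BloomDay`` is an annual-event table.
    """
    physical_dir = Path(physical_dir)
    out = {}
    for path in sorted(physical_dir.glob("*.csv")):
        name = path.stem
        frame = pd.read_csv(path)
        if name == "BloomDay":
            out[name] = normalized_annual_anomaly(frame, base_period, annual_event=True)
            continue
        if name == "SH.WSpd":
            stress = frame.copy()
            stress["value"] = wind_stress(stress["value"].to_numpy())
            out["SH.WStr"] = normalized_annual_anomaly(stress, base_period)
            continue
        if name == "FR.flow":
            pk = (
                peak_flow_day(frame).rename("value").rename_axis("year").reset_index()
            )
            out["FR.pkDay"] = normalized_annual_anomaly(pk, base_period, annual_event=True)
        out[name] = normalized_annual_anomaly(frame, base_period)
    wide = pd.DataFrame(out)
    if year_range is not None:
        wide = wide.loc[(wide.index >= year_range[0]) & (wide.index <= year_range[1])]
    return wide


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifacts; returns them in memory too."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    records = read_records(config.records_csv)
    groups = [c for c in records.columns if c not in _an.METADATA_COLUMNS]
    zoo_wide = _an.compute_anomalies(
        records, groups, base_period=config.climatology, master_seed=config.seed
    )
    selected = _an.select_tows(records)
    selected["TotBiom"] = selected[groups].sum(axis=1)
    tot_biom = _an.compute_anomalies(
        selected, ["TotBiom"], base_period=config.climatology,
        master_seed=config.seed, select=False,
    )["TotBiom"]
    kept, dropped, corr = _an.screen_collinearity(
        zoo_wide, threshold=config.collinearity_threshold
    )
    zoo_screened = zoo_wide[kept]
    zoo_wide.to_csv(out / "zooplankton_annual_anomalies.csv")
    corr.to_csv(out / "zooplankton_correlations.csv")
    artifacts["zooplankton_anomalies"] = zoo_wide
    artifacts["zooplankton_kept"] = kept
    artifacts["zooplankton_dropped"] = dropped
    artifacts["total_biomass_anomaly"] = tot_biom

    phys_wide = physical_anomalies(config.physical_dir, config.climatology)
    p_kept, p_dropped, p_corr = _an.screen_collinearity(
        phys_wide, threshold=config.collinearity_threshold
    )
    phys_screened = phys_wide[p_kept]
    phys_wide.to_csv(out / "physical_annual_anomalies.csv")
    artifacts["physical_anomalies"] = phys_wide
    artifacts["physical_kept"] = p_kept
    artifacts["physical_dropped"] = p_dropped

    results_dfa = {}
    for label, block in (("zooplankton", zoo_screened), ("physical", phys_screened)):
        fits = dfa_model_search(
            block, em_tol=config.dfa_em_tol, max_iter=config.dfa_max_iter,
        )
        table = model_table(fits)
        table.to_csv(out / f"dfa_{label}_model_table.csv", index=False)
        best = fits[0].model
        trends = pd.DataFrame(
            best.trends_.T, index=block.index,
            columns=[f"{label}_trend{i+1}" for i in range(best.trends_.shape[0])],
        )
        loadings = pd.DataFrame(
            best.loadings_, index=block.columns,
            columns=[f"trend{i+1}" for i in range(best.loadings_.shape[1])],
        )
        trends.to_csv(out / f"dfa_{label}_trends.csv")
        loadings.to_csv(out / f"dfa_{label}_loadings.csv")
        results_dfa[label] = {"fits": fits, "table": table, "trends": trends,
                              "loadings": loadings}
    artifacts["dfa"] = results_dfa

    trend_matrix = pd.concat(
        [results_dfa["zooplankton"]["trends"], results_dfa["physical"]["trends"]], axis=1
    ).dropna()
    clusterer = ConstrainedClustering(
        n_random=config.cluster_n_random, seed=config.seed
    ).fit(trend_matrix)
    pd.DataFrame(
        {
            "k": np.arange(1, len(clusterer.zonation_.dispersion_by_k) + 1),
            "within_dispersion": clusterer.zonation_.dispersion_by_k,
        }
    ).to_csv(out / "cluster_dispersion.csv", index=False)
    artifacts["clustering"] = clusterer

    covariates = pd.concat(
        [zoo_screened, tot_biom.rename("TotBiom"), phys_screened], axis=1
    )
    artifacts["covariates"] = covariates

    survival_rows = []
    predictions = {}
    if config.survival_csv:
        surv = pd.read_csv(config.survival_csv)
        models = {}
        for stock, grp in surv.groupby("stock"):
            grp = grp.set_index("ocean_entry_year").sort_index()
            final = grp[grp["status"] == "final"]
            sl = centre_scale(final["survival"])
            X = covariates.loc[covariates.index.intersection(final.index)]
            y = sl.values.reindex(X.index).dropna()
            X = X.loc[y.index].dropna(axis=1)
            search = ArimaRegressionSearch(
                max_subset_size=config.max_covariates,
                cv_repeats=config.cv_repeats, cv_folds=config.cv_folds,
                kpss_alpha=config.kpss_alpha, random_state=config.seed,
                response_name=stock,
            ).fit(X, y)
            models[stock] = search
            if search.best_ is None:
                survival_rows.append({"stock": stock, "model": "none"})
                continue
            b = search.best_
            survival_rows.append(
                {
                    "stock": stock,
                    "covariates": "+".join(b.covariates),
                    "order": str(b.arima_order),
                    "aicc": b.aicc,
                    "ljung_box_p": b.ljung_box_p,
                    "adj_r2": search.adj_r2_,
                    "p_value": search.p_value_,
                    "cv_r2": search.cv_.cv_r2 if search.cv_ else np.nan,
                    "centre": sl.centre,
                    "scale": sl.scale,
                }
            )
            if search.ols_results_ is not None:
                missing_years = covariates.index.difference(y.index)
                new_X = covariates.loc[missing_years, list(b.covariates)]
                preds = search.predict_interval(new_X, back_transform=sl.back_transform)
                preds.to_csv(out / f"predicted_survival_{stock.replace(' ', '_')}.csv")
                predictions[stock] = preds
        pd.DataFrame(survival_rows).to_csv(out / "survival_models.csv", index=False)
        artifacts["survival_models"] = models
        artifacts["survival_predictions"] = predictions

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = manifest
    return artifacts
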