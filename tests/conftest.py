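import pathlib
import tempfile

import pandas as pd
import pytest

from zooptrends import anomalies as an
from zooptrends import pipeline as pl
from zooptrends import synthetic as syn

MASTER_SEED = 42


@pytest.fixture(scope="session")
def spec():
    return syn.GeneratorSpec(master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def zoo_data(spec):
    """(records, truth) from the zooplankton sample generator."""
    return syn.generate_zooplankton_samples(spec, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def zoo_anomalies(spec, zoo_data):
    records, _ = zoo_data
    return an.compute_anomalies(records, list(spec.groups), master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def physical_dir(spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("physical")
    series, truth = syn.generate_physical_series(spec, seed=MASTER_SEED)
    for name, frame in series.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    return out, truth


@pytest.fixture(scope="session")
def phys_anomalies(physical_dir):
    out, _ = physical_dir
    return pl.physical_anomalies(out)


@pytest.fixture(scope="session")
def covariates(spec, zoo_data, zoo_anomalies, phys_anomalies):
    records, _ = zoo_data
    records = records.copy()
    groups = list(spec.groups)
    records["TotBiom"] = records[groups].sum(axis=1)
    tot = an.compute_anomalies(records, ["TotBiom"], master_seed=MASTER_SEED)
    return pd.concat([zoo_anomalies, tot, phys_anomalies], axis=1)


@pytest.fixture(scope="session")
def survival_data(spec, covariates):
    """(table, truth) from the logistic-linear survival generator."""
    return syn.generate_survival(spec, covariates, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def zoo_dfa_search(zoo_anomalies):
    """Full DFA model search over the 12 zooplankton anomaly series."""
    from zooptrends.dfa import dfa_model_search

    return dfa_model_search(zoo_anomalies, max_iter=1500)


@pytest.fixture(scope="session")
def phys_dfa_search(phys_anomalies):
    """Full DFA model search over the screened physical anomaly series."""
    from zooptrends.dfa import dfa_model_search

    kept, _, _ = an.screen_collinearity(phys_anomalies)
    return dfa_model_search(phys_anomalies[kept], max_iter=1500), kept
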