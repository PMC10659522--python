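import numpy as np
import pandas as pd
import pytest

from metaboclock.synthetic import (
    CohortSpec,
    MetaboliteModel,
    default_study,
)


@pytest.fixture(scope="session")
def study():
    """The bundled default study: five cohorts, 40 correlated metabolites,
    population linear-clock R^2 = 0.5, survival, planted outliers."""
    samples, mets, truth = default_study(seed=7)
    return samples, mets, truth


@pytest.fixture(scope="session")
def training_study(study):
    """Default study restricted to trainable (non-birth-cohort) samples with
    planted outliers removed, as the modelling stages see it."""
    samples, mets, truth = study
    keep = mets.index.difference(truth.outlier_ids)
    samples, mets = samples.loc[keep], mets.loc[keep]
    mask = ~samples["birth_cohort"].astype(bool)
    return samples.loc[mask], mets.loc[mask], truth


def make_single_cohort(
    n=500,
    age_range=(30, 70),
    slope=0.0,
    sd=1.0,
    rho=0.0,
    p=4,
    seed=0,
    log_hazard=None,
    batch=1.0,
    name="solo",
):
    """Small single-cohort helper used across unit tests."""
    names = [f"m{j}" for j in range(p)]
    slopes = np.zeros(p)
    slopes[0] = slope
    model = MetaboliteModel(
        names=names,
        base_mean=np.full(p, 50.0),
        base_sd=np.full(p, sd),
        age_slope=slopes,
        blocks=[names],
        rho=rho,
        log_hazard=log_hazard,
    )
    spec = CohortSpec(name, n, age_range, batch_factors=batch)
    return spec, model
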