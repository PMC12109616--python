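import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from bimeta.dataio import ClinicalTable, ExpressionDataset
from bimeta.synthetic import (
    CensoringParams,
    GenotypeParams,
    HazardParams,
    MixtureParams,
    SyntheticConfig,
    simulate_study,
)


@pytest.fixture
def toy_expression() -> ExpressionDataset:
    return ExpressionDataset(
        cohort_id="toy",
        gene_ids=["g1", "g2"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
    )


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    return ClinicalTable(
        cohort_id="toy",
        data=pd.DataFrame(
            {"time": [5.0, 3.0, 8.0, 2.0], "event": [1, 0, 1, 1],
             "age": [60, 70, 55, 65]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        ),
    )


@pytest.fixture(scope="session")
def small_study():
    """Small multi-cohort synthetic study shared across tests (read-only)."""
    config = SyntheticConfig(
        n_cohorts=4,
        n_samples=150,
        n_null_genes=30,
        mixture=MixtureParams(mu_low=0.0, delta=3.0, sigma=1.0, pi_high=0.3),
        hazard=HazardParams(baseline_rate=0.1, log_hr_component=np.log(2.0)),
        censoring=CensoringParams(admin_time=10.0, random_censor_rate=0.05),
        genotype=GenotypeParams(n_null_candidates=10),
        seed=42,
    )
    return simulate_study(config)


@pytest.fixture
def bimodal_sample() -> np.ndarray:
    rng = np.random.default_rng(123)
    return np.concatenate([rng.normal(0.0, 1.0, 700), rng.normal(3.0, 1.0, 300)])
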