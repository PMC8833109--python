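import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from omiclocks import (AssaySpec, DiseaseSpec, RiskFactorSpec,
                       SimulationConfig, qc_pipeline, simulate_cohort,
                       simulate_latent_predictor_bank, split_cohort,
                       stability_select, train_clock)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def one_assay_config(seed, n=800, p=60, age_scale=0.5, delta_scale=0.2,
                     noise=1.0, sigma_delta=5.0, name="assay"):
    """A single-assay design used across the clock tests."""
    return SimulationConfig(
        n_individuals=n, age_range=(16.0, 100.0), sigma_delta=sigma_delta,
        assays=[AssaySpec(name, n_features=p, age_loading_scale=age_scale,
                          delta_loading_scale=delta_scale, noise_sd=noise,
                          batch_levels=2, batch_sd=0.1)],
        risk_factors=[RiskFactorSpec("rf", beta_age=0.3, beta_delta=0.3,
                                     noise_sd=8.0)],
        diseases=[DiseaseSpec("E10-E14", baseline_rate=5e-4,
                              log_hr_age=0.0492, log_hr_delta=0.05)],
        seed=seed)


@pytest.fixture(scope="session")
def bank():
    """Exact latent predictor bank: 600 individuals, 100 predictors."""
    return simulate_latent_predictor_bank(600, 100, seed=31)


@pytest.fixture(scope="session")
def informative_assay():
    """A corrected, standardised assay informative enough for r ~ 0.9 clocks."""
    study = simulate_cohort(one_assay_config(seed=41))
    matrix, _ = qc_pipeline(study.omics[0])
    chron_age = study.cohort["chron_age"]
    split = split_cohort(matrix.individual_ids, seed=41)
    return matrix, chron_age, study.truth["delta"], split


@pytest.fixture(scope="session")
def full_clock(informative_assay):
    matrix, chron_age, _, (train_ids, test_ids) = informative_assay
    return train_clock(matrix, chron_age, train_ids, test_ids,
                       n_lambdas=40, seed=41)


@pytest.fixture(scope="session")
def stability_core(informative_assay):
    matrix, chron_age, _, split = informative_assay
    return stability_select(matrix, chron_age, iterations=120,
                            n_lambdas=30, seed=41, final_split=split)


@pytest.fixture(scope="session")
def large_disease_sim():
    """n=20000 cohort with a single age-driven disease, for Cox recovery."""
    cfg = SimulationConfig(
        n_individuals=20000, age_range=(16.0, 100.0), sigma_delta=5.0,
        assays=[AssaySpec("tiny", n_features=2)],
        diseases=[DiseaseSpec("I10-I15", baseline_rate=3e-4,
                              log_hr_age=0.0492, log_hr_delta=0.0)],
        seed=57)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def oracle_ocaa_sim():
    """n=10000 cohort where the disease depends equally on age and delta."""
    cfg = SimulationConfig(
        n_individuals=10000, age_range=(16.0, 100.0), sigma_delta=5.0,
        assays=[AssaySpec("tiny", n_features=2)],
        diseases=[DiseaseSpec("E10-E14", baseline_rate=4e-4,
                              log_hr_age=0.0492, log_hr_delta=0.0492)],
        seed=63)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
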