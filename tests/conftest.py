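"""Shared fixtures: small generator cohorts and one reusable reduced fit."""

import warnings

import numpy as np
import pytest

from ctxgrowth.model import assemble_design, fit
from ctxgrowth.preprocess import (preprocess_forearm, preprocess_urine,
                                  standardize_age_pooled)
from ctxgrowth.recovery import reduced_spec
from ctxgrowth.synthetic import CohortConfig, simulate_cohort_tables

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def cohort_tables(default_config):
    return simulate_cohort_tables(default_config)


@pytest.fixture(scope="session")
def processed(cohort_tables):
    individuals, forearm, urine, truth = cohort_tables
    proc, excl, sg_ref = preprocess_urine(urine, individuals)
    velocity, eps, n_clamped = preprocess_forearm(forearm, individuals)
    urine_std, vel_std, params = standardize_age_pooled(proc, velocity)
    return {"urine": urine_std, "velocity": vel_std, "params": params,
            "exclusions": excl, "sg_ref": sg_ref, "epsilon": eps,
            "n_clamped": n_clamped}


@pytest.fixture(scope="session")
def small_ctx_fit():
    """One reduced CTX-model fit on a small generator cohort, shared by
    the diurnal, extraction and posterior-predictive tests."""
    config = CohortConfig(seed=0, n_individuals=24, n_urine_individuals=24,
                          n_urine_samples=130, n_sites=4,
                          n_forearm_measurements=120)
    individuals, forearm, urine, _ = simulate_cohort_tables(config)
    proc, _, _ = preprocess_urine(urine, individuals)
    velocity, _, _ = preprocess_forearm(forearm, individuals)
    urine_std, _, _ = standardize_age_pooled(proc, velocity)
    spec = reduced_spec("log_ctx", seed=0, n_iter=900, n_warmup=350,
                        max_treedepth=7)
    design = assemble_design(urine_std, spec)
    return fit(design, spec=spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
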