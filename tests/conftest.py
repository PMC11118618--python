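import numpy as np
import pandas as pd
import pytest

from sleepatlas.synthetic_cohort import (
    IMPUTATION_COVARIATES,
    CohortConfig,
    EffectSpec,
    example_metabolites,
    example_phenotypes,
    generate_cohort,
)
from sleepatlas.preprocess import preprocess_pipeline
from sleepatlas.association import run_scan
from sleepatlas.design_glm import SurveyDesign


def make_design(n, n_strata=5, psus_per_stratum=4, seed=0, weights=None):
    """A valid stratified-cluster design with >= 2 PSUs per stratum."""
    rng = np.random.default_rng(seed)
    psu = np.concatenate(
        [np.arange(n_strata * psus_per_stratum), rng.integers(0, n_strata * psus_per_stratum, n - n_strata * psus_per_stratum)]
    )
    rng.shuffle(psu)
    stratum = psu // psus_per_stratum
    w = rng.uniform(0.5, 3.0, n) if weights is None else np.asarray(weights, float)
    return SurveyDesign(stratum, psu, w)


def imputation_covariates_for(subjects, metab):
    covs = subjects.set_index("subject_id").loc[metab["subject_id"], IMPUTATION_COVARIATES]
    covs.index = metab.index
    return covs


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort with two planted effects, shared across tests."""
    config = CohortConfig(n_subjects=300, seed=42, batch2_covariate_shifts={"age": 9.5})
    phenotypes = example_phenotypes()
    metabolites = example_metabolites(n_metab=20, seed=5)
    effects = [
        EffectSpec("hr_mean_sleep", "met005", slope=0.6),
        EffectSpec("bedtime", "met006", effect_type="circular_sinusoid", amplitude=0.8, acrophase=1.0),
    ]
    subjects, metab, annotation, truth = generate_cohort(config, phenotypes, metabolites, effects)
    return {
        "config": config,
        "phenotypes": phenotypes,
        "metabolites": metabolites,
        "effects": effects,
        "subjects": subjects,
        "metab": metab,
        "annotation": annotation,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_imputation(small_cohort):
    covs = imputation_covariates_for(small_cohort["subjects"], small_cohort["metab"])
    imp, log = preprocess_pipeline(
        small_cohort["metab"], small_cohort["annotation"], covs, m=3, n_iter=5, seed=7
    )
    return imp, log


@pytest.fixture(scope="session")
def small_scan(small_cohort, small_imputation):
    imp, _ = small_imputation
    return run_scan(
        small_cohort["subjects"],
        imp,
        small_cohort["phenotypes"],
        small_cohort["annotation"],
    )
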