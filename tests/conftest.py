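import dataclasses

import numpy as np
import pandas as pd
import pytest

from aeusurv.simulate import (
    CohortConfig,
    GeneConfig,
    TRAIN_COHORT,
    simulate_cohort,
    simulate_gene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """50 patients drawn at the study covariate frequencies."""
    cfg = dataclasses.replace(TRAIN_COHORT, n_patients=50)
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def medium_cohort():
    """200 patients, used by recovery-style tests."""
    cfg = dataclasses.replace(TRAIN_COHORT, n_patients=200)
    return simulate_cohort(cfg, seed=12)


@pytest.fixture
def tiny_clinical():
    """Hand-built 6-patient clinical table covering all therapy levels."""
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(6)],
            "gender": ["male", "female", "male", "female", "male", "female"],
            "race": ["caucasian", "other", "caucasian", "caucasian", "other", "caucasian"],
            "therapy": ["NONE", "CRT", "CRnT", "OTHER", "R", "CRnT"],
            "survival_months": [3.0, 12.0, 24.0, 6.0, 48.0, 18.0],
        }
    )


def make_gene(clinical, seed=1, **kwargs):
    cfg = GeneConfig(gene_id=kwargs.pop("gene_id", "g"), **kwargs)
    return simulate_gene(clinical, cfg, seed=seed)
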