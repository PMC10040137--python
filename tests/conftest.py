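import numpy as np
import pandas as pd
import pytest

from duomethyl.config import CohortConfig, H2Mixture
from duomethyl.simulate import simulate_cohort


@pytest.fixture(scope="session")
def cohort_default():
    """Small default-structure cohort: mixed h2, XCI, 1 latent factor."""
    cfg = CohortConfig(n_pairs=100, n_auto_sites=300, n_x_sites=100, n_latent_factors=1, seed=10)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_null():
    """All-null cohort: no heritability, no sex effects, no latent factors."""
    cfg = CohortConfig(
        n_pairs=100, n_auto_sites=300, n_x_sites=100, n_latent_factors=0,
        h2_distribution=H2Mixture.point_mass(0.0), frac_sex_differential=0.0, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_pairs():
    """Hand-built 6-pair sample sheet with both sexes and varied covariates."""
    return pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(6)],
            "mother_id": [f"M{i}" for i in range(6)],
            "newborn_id": [f"C{i}" for i in range(6)],
            "sex": ["female", "male", "female", "male", "female", "male"],
            "maternal_age": [22.0, 31.0, 27.0, 35.0, 24.0, 29.0],
            "race": ["Black", "non-Black", "Black", "Black", "non-Black", "Black"],
            "smoking": ["no", "yes", "yes", "no", "no", "no"],
            "preterm": ["no", "no", "yes", "no", "no", "yes"],
            "delivery": ["vaginal", "C-section", "vaginal", "vaginal", "C-section", "vaginal"],
            "parity": [1, 2, 1, 3, 2, 1],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
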