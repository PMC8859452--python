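import numpy as np
import pandas as pd
import pytest

from suvtraj import SyntheticCohortSpec, generate_cohort, validate_table

# the Table-1-scale cortical reference used throughout the oracle tests:
# anchor above the logistic floor, cutoff = mean + 2 sd
ANCHOR = 0.863
CUTOFF = 1.045
NORM_MEAN = 0.863
NORM_SD = 0.091


def make_table(rows):
    """Observation table from (subject, time, suvr, sex, apoe, dx, amyloid) rows."""
    return validate_table(
        pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "visit_time",
                "suvr",
                "sex",
                "apoe4_carrier",
                "diagnosis",
                "amyloid_positive",
            ],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject realistic cohort shared by structural tests."""
    spec = SyntheticCohortSpec(n_subjects=120, seed=11)
    table, truth = generate_cohort(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def dense_noise_free_cohort():
    """Noise-free, densely-visited cohort: the pipeline should recover the
    generating trajectory almost exactly on it."""
    spec = SyntheticCohortSpec(
        n_subjects=300, noise_sd=0.0, visits_per_subject=10, visit_spacing=(1.0, 1.5), seed=7
    )
    table, truth = generate_cohort(spec)
    return spec, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
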