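import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mcdt

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Default study-condition cohort (10/17/17, moderate separation)."""
    return mcdt.generate_cohort(mcdt.CohortSpec(seed=7))


@pytest.fixture(scope="session")
def tables(cohort):
    return mcdt.cohort_to_tables(cohort)


@pytest.fixture(scope="session")
def dtc_table(tables):
    features, _ = tables
    return mcdt.compute_dtc_star(features)


@pytest.fixture(scope="session")
def labels(tables):
    _, subjects = tables
    return pd.Series({s.subject_id: s.diagnosis for s in subjects})


@pytest.fixture(scope="session")
def pis(dtc_table, labels):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mcdt.build_all_pis(dtc_table, labels)
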