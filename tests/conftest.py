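import numpy as np
import pytest

from etscc import (
    CohortConfig,
    PKParameters,
    Regimen,
    estimate_cohort,
    fixture_cohort,
    generate_cohort,
)


@pytest.fixture(scope="session")
def fixture_tables():
    """Deterministic 33-patient reference cohort (cohort table, CT table)."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def fixture_results(fixture_tables):
    """Per-patient eTSCC results on the reference cohort."""
    cohort, ct = fixture_tables
    results, exclusions = estimate_cohort(cohort, ct)
    assert len(exclusions) == 0
    return results


@pytest.fixture(scope="session")
def default_regimen():
    """Standard FOLFOX cycle for a BSA 1.8 m^2 patient."""
    return Regimen(bsa=1.8, n_cycles=4, span_hours=1726.0)


@pytest.fixture(scope="session")
def pk_defaults():
    return PKParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210444)
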