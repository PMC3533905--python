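import pytest
from hypothesis import HealthCheck, settings

from perilink.admission_rules import load_vocabulary
from perilink.synthetic_cohort import CohortParams, ErrorModel, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


def zero_error_params(n=400, seed=7, **kw):
    """Cohort configuration whose exact-match join recovers truth perfectly."""
    defaults = dict(
        n_deliveries=n,
        seed=seed,
        maternal_nonadmission_rate=0.0,
        stillbirth_misclassification_rate=0.0,
        code_missing_rate=0.0,
    )
    defaults.update(kw)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def zero_cohort():
    """Error-free cohort: the deterministic oracle for downstream modules."""
    return generate_cohort(zero_error_params(), ErrorModel.zero())


@pytest.fixture(scope="session")
def default_cohort():
    """Small cohort under the default error model."""
    return generate_cohort(CohortParams(n_deliveries=500, seed=11), ErrorModel())
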