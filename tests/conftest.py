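import pytest

from ruleout.cohort import TestResult

# `TestResult` is a domain enum, not a test class
TestResult.__test__ = False

from ruleout import (
    apply_eligibility_flow,
    build_confusion,
    select_performance_set,
    study_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """The deterministic 488-record reference cohort."""
    return study_cohort()


@pytest.fixture(scope="session")
def eligible(cohort):
    records, _ = apply_eligibility_flow(cohort)
    return records


@pytest.fixture(scope="session")
def analyzable(eligible):
    records, _ = select_performance_set(eligible)
    return records


@pytest.fixture(scope="session")
def verified_counts(analyzable):
    return build_confusion(analyzable)
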