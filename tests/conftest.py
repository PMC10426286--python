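import pytest

import miscvar as mv
from miscvar import fixtures


@pytest.fixture(scope="session")
def roster():
    return fixtures.study_roster()


@pytest.fixture(scope="session")
def study_cohort(roster):
    return fixtures.load_study_cohort(roster=roster)


@pytest.fixture(scope="session")
def registry():
    return fixtures.load_study_panels()


@pytest.fixture(scope="session")
def study_cands(study_cohort, registry):
    """The candidate set retained from the packaged study table."""
    return mv.prioritize_cohort(study_cohort, registry)
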