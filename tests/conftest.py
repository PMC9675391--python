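import pytest

from tumorboard.rulebook import load_rulebook
from tumorboard.synthetic import generate_cohort


@pytest.fixture(scope="session")
def default_rulebook():
    return load_rulebook()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-patient synthetic cohort (seeded, shared read-only)."""
    return generate_cohort()
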