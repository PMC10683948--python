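import pytest

from nephrocog import GeneratorConfig, generate_cohort
from nephrocog.pipeline import prepare_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Prepared default cohort (n=4000) with its ground truth."""
    table, truth = generate_cohort(GeneratorConfig(n_participants=4000, seed=11))
    return prepare_cohort(table), truth


@pytest.fixture(scope="session")
def small_cohort():
    """Smaller prepared cohort for cheaper model fits."""
    table, truth = generate_cohort(GeneratorConfig(n_participants=1500, seed=23))
    return prepare_cohort(table), truth


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (n=100k) for tight parameter-recovery checks."""
    table, truth = generate_cohort(GeneratorConfig(n_participants=100_000, seed=5))
    return table, truth
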