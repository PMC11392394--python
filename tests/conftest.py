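import pytest

from ventalloc.cohort import CohortSpec, generate_cohort
from ventalloc.life_expectancy import annotate_cohort, default_life_table


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def small_cohort(life_table):
    """Annotated synthetic cohort of 400 encounters (fast unit-test fixture)."""
    cohort = generate_cohort(CohortSpec(n=400, seed=5))
    return annotate_cohort(cohort, life_table)


@pytest.fixture(scope="session")
def default_cohort(life_table):
    """Annotated default-size synthetic cohort shared by the heavier tests."""
    cohort = generate_cohort(CohortSpec(n=3707, seed=42))
    return annotate_cohort(cohort, life_table)


@pytest.fixture(scope="session")
def large_cohort():
    """Unannotated 50k cohort for calibration / parameter-recovery checks."""
    return generate_cohort(CohortSpec(n=50_000, seed=11))
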