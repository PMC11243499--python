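import pytest

from wbqn.config import ScoringConfig
from wbqn.foods import default_food_table
from wbqn.scoring import score_frame
from wbqn.simulate import default_cohort_config, generate_cohort


@pytest.fixture(scope="session")
def foods():
    return default_food_table()


@pytest.fixture()
def config():
    return ScoringConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 529-woman synthetic cohort, seed 42."""
    return generate_cohort(default_cohort_config(seed=42))


@pytest.fixture(scope="session")
def scored_default(default_cohort):
    return score_frame(default_cohort.frame, default_cohort.foods,
                       ScoringConfig())
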