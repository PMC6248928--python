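import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from baks import tune_alpha, tuning_scenarios

settings.register_profile(
    "baks",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("baks")

ALPHA_GRID = np.arange(1.0, 10.0 + 0.25, 0.5)
TUNING_SEED = 0
TUNING_REPS = 20


@pytest.fixture(scope="session")
def tuning_run():
    """One reduced-size tuning sweep shared by the evaluation and acceptance
    tests: the six benchmark scenarios at 20 repetitions each, alpha grid
    1..10 in steps of 0.5, beta = n^(4/5)."""
    return tune_alpha(ALPHA_GRID, tuning_scenarios(TUNING_REPS), seed=TUNING_SEED)
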