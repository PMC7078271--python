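import numpy as np
import pandas as pd
import pytest

from sleepcog import CohortConfig, PatternSequence, fit_composite, generate_cohort


@pytest.fixture(scope="session")
def pattern() -> PatternSequence:
    return PatternSequence((2, 1, 3, 4))


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    """Default synthetic cohort (seed 0) with the composite column added."""
    table, _ = generate_cohort(CohortConfig(), seed=0)
    comp = fit_composite(
        table["psqi"].to_numpy(float), table["ais"].to_numpy(float)
    )
    table = table.copy()
    table["sleep_disturbance"] = comp.scores
    return table


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
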