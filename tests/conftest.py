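import itertools

import numpy as np
import pandas as pd
import pytest

from discountkit import CohortSpec, TaskConfig

#: discount rates (per day) spanning shallow to steep discounting
K_TRUE_GRID = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.2)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=20240129)


@pytest.fixture(scope="session")
def all_choice_sequences(config):
    """All 2^6 titration choice sequences for one delay series."""
    return list(itertools.product(("present", "future"), repeat=config.trials_per_delay))


@pytest.fixture
def small_ancova_fixture():
    """Hand-built 12-row, 3-group dataset for oracle comparisons."""
    rng = np.random.default_rng(42)
    groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    age = np.array([12.0, 15.0, 19.0, 24.0, 13.0, 17.0, 21.0, 28.0, 11.0, 16.0, 22.0, 29.0])
    y = np.array([-6.2, -5.8, -7.1, -6.5, -7.9, -7.2, -8.1, -6.9, -5.1, -5.6, -4.8, -6.0])
    y = y + 0.01 * rng.normal(size=12)  # break any accidental structure
    return pd.DataFrame({"ln_k": y, "group": groups, "age": age})
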