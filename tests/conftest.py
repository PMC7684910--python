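import numpy as np
import pandas as pd
import pytest

from qrfcost.synthetic import default_config, generate_episodes

#: the eight cost-determinant covariates the generator gives nonzero effects
SIGNAL_COVARIATES = [
    "chemo_drug",
    "surgery",
    "insurance",
    "radiation",
    "comorbidity_cat",
    "clean_period_cat",
    "age",
    "hrr_relative_cost",
]

NULL_COVARIATES = ["sex", "trial", "institutional"]


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    """Default-calibrated synthetic episodes, small enough for unit tests."""
    return generate_episodes(default_config(n_episodes=250, seed=42))


@pytest.fixture(scope="session")
def full_table() -> pd.DataFrame:
    """One default-calibrated table at the study sample size."""
    return generate_episodes(default_config(seed=0))


@pytest.fixture()
def toy_split_table() -> pd.DataFrame:
    """20 rows whose response is exactly determined by a binary covariate."""
    rng = np.random.default_rng(7)
    x = np.repeat([0.0, 1.0], 10)
    rng.shuffle(x)
    return pd.DataFrame({"x1": x, "cost": 5.0 + 10.0 * x})
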