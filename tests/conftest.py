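import numpy as np
import pytest

from score2val.engine import load_model_specs
from score2val.simulate import generate, scenario_config


@pytest.fixture(scope="session")
def specs():
    return load_model_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-scenario cohort shared by pipeline-level tests."""
    cfg = scenario_config(
        "table1_default", seed=5, n_by_sex={"male": 4000, "female": 4000}
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def midsize_cohort():
    """A mid-size default cohort for distribution-level checks."""
    cfg = scenario_config(
        "table1_default", seed=7, n_by_sex={"male": 20000, "female": 20000}
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
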