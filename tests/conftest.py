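import numpy as np
import pytest

from pscea.pipeline import RunConfig, fit_selections, run_base_case
from pscea.synthetic import trial_like_bundle


@pytest.fixture(scope="session")
def bundle():
    """Synthetic trial workspace: four digitized curves + parameter table."""
    return trial_like_bundle(seed=1)


@pytest.fixture(scope="session")
def selections(bundle):
    """AIC selections for all four curves (expensive; fit once)."""
    return fit_selections(bundle.curves)


@pytest.fixture(scope="session")
def base_config():
    return RunConfig(seed=1, psa_n_draws=50)


@pytest.fixture(scope="session")
def base_case(bundle, selections, base_config):
    return run_base_case(base_config, bundle.curves, bundle.parameters, selections=selections)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
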