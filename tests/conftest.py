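import numpy as np
import pytest

from zebrafit import default_zebra_scheme
from zebrafit.fitting import FitConfig, GridEvaluator


@pytest.fixture(scope="session")
def scheme():
    return default_zebra_scheme()


@pytest.fixture(scope="session")
def ivim_config():
    return FitConfig.default("t2s_ivim")


@pytest.fixture(scope="session")
def adc_config():
    return FitConfig.default("t2s_adc")


@pytest.fixture(scope="session")
def ivim_evaluator(scheme, ivim_config):
    """Shared grid design matrix; building it dominates single-voxel cost."""
    return GridEvaluator("t2s_ivim", ivim_config.grid, scheme)


@pytest.fixture(scope="session")
def adc_evaluator(scheme, adc_config):
    return GridEvaluator("t2s_adc", adc_config.grid, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230515)
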