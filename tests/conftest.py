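import numpy as np
import pytest

from psmcea.model import CEModel, load_config
from psmcea.survival import ParametricSurvival

# the two fitted reference-arm distributions the shipped analysis is built on
PFS_LOGNORMAL = (1.121355, 0.7702185)
OS_LOGLOGISTIC = (0.01822555, 1.694566)


@pytest.fixture(scope="session")
def pfs_model() -> ParametricSurvival:
    return ParametricSurvival("lognormal", PFS_LOGNORMAL)


@pytest.fixture(scope="session")
def os_model() -> ParametricSurvival:
    return ParametricSurvival("loglogistic", OS_LOGLOGISTIC)


@pytest.fixture(scope="session")
def config() -> dict:
    return load_config()


@pytest.fixture(scope="session")
def ce_model(config) -> CEModel:
    return CEModel(config)


@pytest.fixture()
def example_curves():
    """One representative parameter set per family, for invariant sweeps."""
    return [
        ParametricSurvival("exponential", (0.07,)),
        ParametricSurvival("weibull", (1.3, 12.0)),
        ParametricSurvival("lognormal", PFS_LOGNORMAL),
        ParametricSurvival("loglogistic", OS_LOGLOGISTIC),
        ParametricSurvival("gompertz", (0.05, 0.04)),
        ParametricSurvival("gengamma", (2.0, 0.8, 0.5)),
        ParametricSurvival("gengamma", (2.0, 0.8, -0.7)),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220209)
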