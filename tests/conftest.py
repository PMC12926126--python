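import logging

import numpy as np
import pytest

from survcea.ipd import PseudoIPD
from survcea.pipeline import RunConfig, build_model
from survcea.synthetic import make_fixture_study

logging.getLogger("survcea").setLevel(logging.ERROR)


def weibull_arm(seed: int, n: int = 200, shape: float = 1.4, median: float = 8.0,
                censor_scale: float = 2.2) -> PseudoIPD:
    """Weibull event times with uniform censoring (~10-20% censored)."""
    rng = np.random.default_rng(seed)
    scale = median / np.log(2.0) ** (1.0 / shape)
    T = scale * rng.weibull(shape, n)
    C = rng.uniform(0, np.quantile(T, 0.99) * censor_scale, n)
    obs = np.minimum(T, C)
    ev = (T <= C).astype(int)
    return PseudoIPD(tuple(zip(np.maximum(obs, 1e-5), ev)), "a", "OS")


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_study()


@pytest.fixture(scope="session")
def fitted():
    """The assembled CEA model for the packaged synthetic study."""
    model, selections = build_model(RunConfig())
    return model, selections


@pytest.fixture(scope="session")
def model(fitted):
    return fitted[0]


@pytest.fixture(scope="session")
def weibull_ipd():
    return weibull_arm(5, n=150)
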