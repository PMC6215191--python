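import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cyanoval as cv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def models():
    return cv.default_models()


@pytest.fixture(scope="session")
def mclr(models):
    return models["MC-LR"]


@pytest.fixture(scope="session")
def design():
    return cv.StudyDesign()


@pytest.fixture(scope="session")
def bundle(models, design):
    """Full synthetic validation bundle, fixed seed."""
    return cv.simulate.simulate_bundle(models, design, seed=7)


def ols_oracle(x, y):
    """Normal-equations straight-line fit, independent of the library path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = y.mean() - b * x.mean()
    return a, b
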