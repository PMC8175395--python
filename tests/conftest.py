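import numpy as np
import pytest

import sorptionlab as sl


@pytest.fixture(scope="session")
def published_quadratic() -> sl.QuadraticModel:
    """Published quadratic removal-efficiency model (actual units)."""
    return sl.PUBLISHED_QUADRATIC


@pytest.fixture(scope="session")
def factor_space() -> sl.FactorSpace:
    return sl.DEFAULT_FACTOR_SPACE


@pytest.fixture(scope="session")
def box(factor_space) -> list[tuple[float, float]]:
    return factor_space.bounds


@pytest.fixture(scope="session")
def langmuir_ref() -> sl.IsothermSpec:
    return sl.REFERENCE_ISOTHERMS_NL["langmuir"]


@pytest.fixture(scope="session")
def noiseless_surface_sample(factor_space, published_quadratic):
    """400 noiseless samples of the quadratic surface over the factor box."""
    rng = np.random.default_rng(42)
    lo = np.array([b[0] for b in factor_space.bounds])
    hi = np.array([b[1] for b in factor_space.bounds])
    X = rng.uniform(lo, hi, size=(400, 4))
    y = sl.predict_quadratic(published_quadratic, X)
    return X, y
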