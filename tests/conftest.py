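import numpy as np
import pytest

from malnut.model import ModelParameters, NoiseIntensities, StateVector
from malnut.paths import baseline_scenario


@pytest.fixture(scope="session")
def baseline():
    return baseline_scenario()


@pytest.fixture(scope="session")
def table_params(baseline):
    return baseline.params


@pytest.fixture(scope="session")
def study_noise(baseline):
    return baseline.noise


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_valid_params(rng, n=1):
    """Random positive parameter sets for property checks."""
    out = []
    for _ in range(n):
        v = rng.uniform(0.01, 1.0, size=11)
        out.append(
            ModelParameters(
                B=v[0], eps=v[1], lam_b=v[2], lam_g=v[3], theta=v[4], theta_b=v[5],
                gam_b=v[6], gam_g=v[7], chi_b=v[8], chi_g=v[9], del_g=v[10],
            )
        )
    return out if n > 1 else out[0]
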