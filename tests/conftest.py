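import numpy as np
import pytest

from rocselect.data import TwoGroupSample, center_two_group


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_sample(rng, n_nd=6, n_d=6, d=2, sigma=1.0, theta_nd=None, theta_d=None):
    """Small synthetic two-group draw with standard-normal covariates."""
    theta_nd = np.zeros(d) if theta_nd is None else np.asarray(theta_nd, float)
    theta_d = np.zeros(d) if theta_d is None else np.asarray(theta_d, float)
    z_nd = rng.standard_normal((n_nd, d))
    z_d = rng.standard_normal((n_d, d))
    y_nd = z_nd @ theta_nd + sigma * rng.standard_normal(n_nd)
    y_d = z_d @ theta_d + sigma * rng.standard_normal(n_d)
    return TwoGroupSample(
        y_nondiseased=y_nd, y_diseased=y_d, z_nondiseased=z_nd, z_diseased=z_d
    )


@pytest.fixture
def toy_centered(rng):
    return center_two_group(random_sample(rng, n_nd=8, n_d=8, d=2, theta_nd=[1, 0], theta_d=[2, 0.5]))
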