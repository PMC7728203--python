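import numpy as np
import pytest

from ramify.kernels import MGDParams, build_angular_grid


@pytest.fixture(scope="session")
def sphere_2k():
    return build_angular_grid(2000)


@pytest.fixture(scope="session")
def sphere_10k():
    return build_angular_grid(10000)


def random_kernel(rng, max_cond=50.0, mu_scale=1.0):
    """Random covariance with condition number <= max_cond and a Gaussian
    mean; used across the directional-statistics tests."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    log_lo, log_hi = 0.0, np.log(max_cond)
    lam = np.exp(rng.uniform(log_lo, log_hi, size=3))
    lam = lam / lam.max()  # eigenvalues in (1/max_cond, 1]
    sigma = (q * lam) @ q.T
    mu = mu_scale * rng.standard_normal(3)
    return MGDParams(mu, sigma)
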