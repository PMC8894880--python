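import numpy as np
import pytest

from fixnet import synthgen as sg


@pytest.fixture(scope="session")
def grid20():
    return sg.grid_mesh(20, 20, 6.2)


@pytest.fixture(scope="session")
def grid8():
    return sg.grid_mesh(8, 8, 6.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_stable_model(rng, n_max=8, p_max=5, radius=0.9):
    """Random stable MVAR lag stack: coefficients rescaled inside the unit circle."""
    from fixnet.mvar_gpdc import spectral_radius

    n = int(rng.integers(2, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    A = rng.normal(scale=0.4, size=(p, n, n))
    rho = spectral_radius(A)
    if rho >= radius:
        scale = radius / rho
        A *= scale ** np.arange(1, p + 1)[:, None, None]
    sigma2 = rng.uniform(0.2, 3.0, size=n)
    return A, sigma2
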