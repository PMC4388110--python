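import numpy as np
import pytest

from opmgrf import make_atomic_spectrum, make_uniform_annulus


@pytest.fixture
def mono():
    """Monochromatic ring at unit wavenumber (lambda_sq = 2*pi)."""
    return make_atomic_spectrum([1.0], [1.0])


@pytest.fixture
def mono_unit_lambda():
    """Monochromatic ring with lambda_sq = 1."""
    return make_atomic_spectrum([2.0 * np.pi], [1.0])


@pytest.fixture
def annulus():
    return make_uniform_annulus(9.0, 11.0)


def random_atomic_spectrum(rng, max_atoms=6):
    """A random atomic spectral measure (shared helper for property tests)."""
    n = int(rng.integers(1, max_atoms + 1))
    radii = rng.uniform(0.2, 20.0, size=n)
    while np.unique(radii).size != n:
        radii = rng.uniform(0.2, 20.0, size=n)
    weights = rng.uniform(0.05, 1.0, size=n)
    return make_atomic_spectrum(radii, weights)
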