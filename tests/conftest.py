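import numpy as np
import pytest

from usreg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_case():
    """A 32^3 phantom shared by fast unit tests."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32), n_landmarks=8, seed=11))


@pytest.fixture(scope="session")
def medium_case():
    """A 48^3 phantom for registration tests."""
    return generate_phantom(PhantomSpec(shape=(48, 48, 48), seed=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def assert_descending(log):
    """Every optimization log must have a non-increasing objective."""
    J = log.objective
    assert all(a >= b - 1e-12 for a, b in zip(J, J[1:])), "objective increased"
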