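import numpy as np
import pytest

from pnadyn.core import build_duplex
from pnadyn.systems import (CoarseModelParams, make_duplex_system,
                            make_ss_system)


@pytest.fixture(scope="session")
def hexamer_duplex():
    return build_duplex("GAACTC", "GAGTTC")


@pytest.fixture(scope="session")
def default_params():
    return CoarseModelParams()


@pytest.fixture(scope="session")
def ss_system():
    return make_ss_system("GAACTC", "pna")


@pytest.fixture(scope="session")
def gamma_system():
    return make_ss_system("GAACTC", "gamma_pna")


@pytest.fixture(scope="session")
def duplex_system(hexamer_duplex):
    return make_duplex_system(hexamer_duplex)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_conformation(rng, n_sites, scale=1.0):
    from pnadyn.core import Conformation

    return Conformation(scale * rng.normal(size=(n_sites, 3)))


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(size=3, scale=2.0)
    return Q, t
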