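import numpy as np
import pytest

import kinmodes as km


@pytest.fixture(scope="session")
def pgi():
    return km.make_pgi_module()


@pytest.fixture(scope="session")
def pgi_steady():
    """Low-sugar PGI variant relaxed to its closed-system steady state."""
    module = km.make_pgi_module(g6p=0.005, f6p=0.002)
    state = km.find_steady_state(module.network, module.state)
    return module, state


@pytest.fixture(scope="session")
def g6pdh():
    return km.make_g6pdh_module()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def random_stable_matrix(rng, m=8, diag_scale=4.0):
    """Random strictly-stable matrix: negative dominant-ish diagonals."""
    A = rng.standard_normal((m, m))
    A -= np.diag(np.diag(A))
    A += np.diag(-diag_scale * (1.0 + rng.uniform(size=m) * np.abs(A).sum(axis=1)))
    return A


def matrix_with_spectrum(rng, eigenvalues, cond_limit=50.0):
    """Diagonalizable matrix with a prescribed real spectrum."""
    m = len(eigenvalues)
    while True:
        P = rng.standard_normal((m, m))
        if np.linalg.cond(P) < cond_limit:
            break
    return P @ np.diag(np.asarray(eigenvalues, float)) @ np.linalg.inv(P)
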