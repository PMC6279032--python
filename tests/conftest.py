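import numpy as np
import pytest

from dynalign import build_hessian, extract_nodes, slow_modes
from dynalign import fixtures as fx


def random_rotation(rng):
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def bundle():
    """3-helix, 36-node compact bundle (globular-fold surrogate)."""
    return fx.make_bundle(3, 12)


@pytest.fixture(scope="session")
def bundle_nodes(bundle):
    return extract_nodes(bundle)


@pytest.fixture(scope="session")
def bundle_modes(bundle_nodes):
    return slow_modes(build_hessian(bundle_nodes), n_keep=12)
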