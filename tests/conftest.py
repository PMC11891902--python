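import numpy as np
import pytest

import hamartini as hm


@pytest.fixture(scope="session")
def glcnac_top():
    return hm.build_monomer_topology("GlcNAc")


@pytest.fixture(scope="session")
def glca_top():
    return hm.build_monomer_topology("GlcA")


@pytest.fixture(scope="session")
def chain4():
    return hm.build_chain_topology(4)


@pytest.fixture(scope="session")
def chain8():
    return hm.build_chain_topology(8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
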