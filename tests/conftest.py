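import numpy as np
import pytest

from bmcshell import synthetic
from bmcshell.lattice import HexamerPair, TriHexamerModel


@pytest.fixture(scope="session")
def lmap():
    return synthetic.toy_landmark_map()


@pytest.fixture(scope="session")
def toy_hexamer():
    return synthetic.make_toy_hexamer(seed=0)


@pytest.fixture(scope="session")
def arr_a_lattice():
    """Two-hexamer head-on layer at the tight (Arr-A-like) spacing."""
    return synthetic.make_lattice(synthetic.ToyLatticeSpec(spacing=68.5), n_hex=2)


@pytest.fixture(scope="session")
def arr_a_pair(arr_a_lattice):
    return HexamerPair(arr_a_lattice.hexamers[0], arr_a_lattice.hexamers[1])


@pytest.fixture(scope="session")
def trihex_lattice():
    return synthetic.make_lattice(synthetic.ToyLatticeSpec(spacing=68.5), n_hex=3)


@pytest.fixture(scope="session")
def trihex(trihex_lattice):
    h = trihex_lattice.hexamers
    return TriHexamerModel(
        hexamers=list(h),
        pairs=[HexamerPair(h[0], h[1]), HexamerPair(h[0], h[2]),
               HexamerPair(h[1], h[2])],
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-50, 50, 3)
    return rot, trans
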