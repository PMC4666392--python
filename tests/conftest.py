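import numpy as np
import pytest

import filamentforge as ff


@pytest.fixture(scope="session")
def default_model():
    """The principal starting structure: two site-II triplets (8 bp
    positioned for testing once the 6-bp tails are counted in) flanked by
    B-form tails through 90° junctions."""
    return ff.build_synaptic_model("T" * 20, ff.TripletPattern(2, 6, 6))


@pytest.fixture(scope="session")
def postsynaptic():
    return ff.make_postsynaptic_reference(9)


@pytest.fixture(scope="session")
def filament_strand_18():
    return ff.build_filament_strand("T" * 18)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rigid(rng):
    """A uniformly random rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-30, 30, size=3)
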