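import numpy as np
import pytest

from tcrmotion import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_tcr():
    return sd.make_toy_tcr(seed=101)


@pytest.fixture(scope="session")
def toy_pmhc():
    return sd.make_toy_pmhc(seed=202, anchor_mode="P2_P9")


@pytest.fixture(scope="session")
def toy_complex():
    return sd.make_toy_complex(seed=303, anchor_mode="P2_P9")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_cloud(rng, n=10, scale=5.0):
    """A well-conditioned random point cloud."""
    return rng.normal(scale=scale, size=(n, 3))


def random_rigid(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
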