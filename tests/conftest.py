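import numpy as np
import pytest

from lungreg import phantoms as ph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """A 32^3 phantom pair shared by driver/solver tests."""
    return ph.make_pair(shape=(32, 32, 32), seed=3, max_disp_voxels=5,
                        smoothness=5.0, n_keypoints=30)


def finite_difference_grad(f, x, h=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += h
        xm = x.copy()
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g
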