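import numpy as np
import pytest

from dlradiomics.io_preproc import Mask, Volume
from dlradiomics.synthetic import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def small_case():
    """One deterministic HCC-like phantom case."""
    spec = PhantomSpec(n_cases=1, seed=7)
    return generate_case(0, spec, np.random.default_rng(7), "fix_case")


@pytest.fixture
def sphere_mask():
    """Discrete sphere of radius 10 mm in a 28^3 grid at 1 mm spacing."""
    r = 10.0
    n = 28
    c = (n - 1) / 2.0
    zz = np.indices((n, n, n))
    dist = np.sqrt(((zz - c) ** 2).sum(axis=0))
    return Mask(dist <= r)


def random_voi(rng, max_shape=4, max_levels=4):
    """Random small discretised VOI; guaranteed at least one in-mask voxel."""
    shape = tuple(rng.integers(1, max_shape + 1, size=3))
    lv = rng.integers(0, max_levels + 1, size=shape)
    if not (lv > 0).any():
        lv.flat[rng.integers(0, lv.size)] = 1
    return lv


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
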