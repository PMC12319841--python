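import numpy as np
import pytest

from boldwalk import SubstrateSet, VoxelPhantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_phantom():
    """Single substrate, zero field, 100 um cube."""
    g = (8, 8, 8)
    return VoxelPhantom(
        np.zeros(g, dtype=np.uint8), np.zeros(g, dtype=np.float32), [100.0] * 3
    )


@pytest.fixture
def random_field_phantom():
    """Single substrate with a frozen random off-resonance map (Tesla at 1 T)."""
    g = (8, 8, 8)
    rng = np.random.default_rng(77)
    db0 = (rng.standard_normal(g) * 1e-7).astype(np.float32)
    return VoxelPhantom(np.zeros(g, dtype=np.uint8), db0, [100.0] * 3)


@pytest.fixture
def halfspace_phantom():
    """Two half-space substrates split along x in a 200 um box."""
    g = (200, 4, 4)
    sub = np.zeros(g, dtype=np.uint8)
    sub[100:] = 1
    return VoxelPhantom(sub, np.zeros(g, dtype=np.float32), [200.0] * 3)


@pytest.fixture
def single_substrate_set():
    return SubstrateSet(t1=[2000.0], t2=[41.0], d=[1.0])
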