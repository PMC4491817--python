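import numpy as np
import pytest
from hypothesis import settings

from npctomo.phantom import BENCH_VOXEL_A, PorePhantom, make_npc_density
from npctomo.volume import Volume

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bench_phantom() -> Volume:
    """64-voxel NPC density at benchmark sampling (26.4 Å voxels)."""
    return make_npc_density(PorePhantom(box=64, voxel_size=BENCH_VOXEL_A))


@pytest.fixture(scope="session")
def small_phantom() -> Volume:
    """32-voxel NPC density (52.8 Å voxels) for fast alignment tests."""
    return make_npc_density(PorePhantom(box=32, voxel_size=2 * BENCH_VOXEL_A))


@pytest.fixture()
def smooth_blob() -> np.ndarray:
    """Smooth asymmetric multi-Gaussian test volume (32 voxels)."""
    n = 32
    c = n // 2
    x, y, z = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
    data = (np.exp(-((x - 4) ** 2 + (y - 1) ** 2 + z ** 2) / 18)
            + 0.8 * np.exp(-((x + 3) ** 2 + (y + 4) ** 2 + (z - 3) ** 2) / 30)
            + 0.6 * np.exp(-(x ** 2 + (y - 5) ** 2 + (z + 4) ** 2) / 12))
    return data.astype(np.float32)
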