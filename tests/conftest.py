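import numpy as np
import pytest

from depotkit.phantoms import DepotSpec, make_depot_phantom
from depotkit.volumetric import BinaryMask


def make_ball_mask(radius_mm: float = 10.0, spacing: float = 0.5) -> BinaryMask:
    """Voxelized ball centred on the grid; the shared analytic shape oracle."""
    n = int(np.ceil(radius_mm / spacing)) + 3
    ax = np.arange(-n, n + 1) * spacing
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return BinaryMask(x**2 + y**2 + z**2 <= radius_mm**2, (spacing,) * 3)


@pytest.fixture(scope="session")
def ball_mask():
    return make_ball_mask()


@pytest.fixture(scope="session")
def default_phantom():
    """Uniform 40 mg/mL ellipsoidal depot at test-friendly resolution."""
    return make_depot_phantom(DepotSpec(spacing=0.75, seed=7))
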