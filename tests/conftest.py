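import numpy as np
import pytest

from sfproj import (
    RomSpec,
    default_rig_geometry,
    generate_rom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20220712)


@pytest.fixture(scope="session")
def one_dof_set():
    """Rotations about X on a 1-degree grid over +-30 degrees."""
    return generate_rom(RomSpec("one_dof", (30.0, 0.0, 0.0), "XYZ", grid_step=1.0))


@pytest.fixture(scope="session")
def two_dof_set():
    """Independent +-30 (X) / +-15 (Y) ranges, 2.5-degree grid."""
    return generate_rom(RomSpec("two_dof", (30.0, 15.0, 0.0), "XYZ", grid_step=2.5))


@pytest.fixture(scope="session")
def rig_geometry():
    return default_rig_geometry()


def random_orientations(rng, n):
    from scipy.spatial.transform import Rotation as R

    from sfproj import Orientation

    return [Orientation.from_rotation(m) for m in R.random(n, rng=rng).as_matrix()]
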