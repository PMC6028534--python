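import numpy as np
import pytest

from condensinmap import synthetic_data as syn

ISO20 = (20.0, 20.0, 20.0)


@pytest.fixture(scope="session")
def straight_tube_20nm():
    """Straight 2-µm flat-ended tube mask on a 20-nm isotropic grid."""
    axis = syn.straight_axis(2000.0) + np.array([300.0, 400.0, 300.0])
    mask = syn.tube_mask(axis, 200.0, (30, 40, 140), ISO20)
    return axis, mask


@pytest.fixture(scope="session")
def quarter_circle_tube_20nm():
    """Quarter-circle tube (radius 2 µm) mask on a 20-nm isotropic grid."""
    axis = syn.arc_axis(2000.0) + np.array([300.0, 400.0, 400.0])
    mask = syn.tube_mask(axis, 200.0, (30, 150, 150), ISO20)
    return axis, mask


@pytest.fixture(scope="session")
def gaussian_tube_100nm():
    """Rendered tube with radial Gaussian sigma = 100 nm plus its axis mask."""
    axis = syn.straight_axis(4000.0) + np.array([400.0, 1000.0, 600.0])
    shape = (40, 100, 260)
    stack = syn.render_tube(axis, 100.0, shape, ISO20)
    mask = syn.tube_mask(axis, 200.0, shape, ISO20)
    return axis, stack, mask
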