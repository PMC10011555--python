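import numpy as np
import pytest

from fiberorient3d import frangi3d, masking
from fiberorient3d.phantoms import make_cylinder, make_fiber_stack


@pytest.fixture(scope="session")
def z_cylinder():
    """Radius 2.5 um cylinder along z at 1 um voxels."""
    return make_cylinder(2.5, aspect_ratio=8, px_per_um=1.0, pad_um=6.0)


@pytest.fixture(scope="session")
def z_cylinder_result(z_cylinder):
    return frangi3d.multiscale_frangi(z_cylinder.volume, [1.0, 1.25, 1.5])


@pytest.fixture(scope="session")
def fiber_stack():
    """Small validation-style stack of near-y fibers."""
    return make_fiber_stack(shape_um=(40.0, 80.0, 80.0), n_fibers=6, seed=4)


@pytest.fixture(scope="session")
def enhanced_field(fiber_stack):
    res = frangi3d.multiscale_frangi(fiber_stack.volume, [1.0, 1.25, 1.5])
    masks = masking.MaskSet(masking.li_fiber_mask(res.vesselness))
    return masking.apply_masks(res, masks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
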