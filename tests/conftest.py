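import numpy as np
import pytest

from ventridisp.phantom import PhantomSpec, make_subject, make_template
from ventridisp.volume_io import voxel_to_world


@pytest.fixture(scope="session")
def template():
    """Default 64^3 @ 2 mm head phantom and its ventricle mask."""
    return make_template()


@pytest.fixture(scope="session")
def lateral_phantom():
    """One tumor-bearing subject with a right-lateral tumor and its truth."""
    spec = PhantomSpec(tumor_center=(25.0, 10.0, 6.0), tumor_radius=12.0,
                       amplitude=8.0, seed=11, noise_sd=0.02)
    image, tumor, truth = make_subject(spec)
    return spec, image, tumor, truth


def brute_force_com(mask):
    """Loop-based center of mass over all voxels (independent oracle)."""
    num = np.zeros(3)
    den = 0.0
    for idx in np.ndindex(*mask.grid.shape):
        w = mask.weights[idx]
        if w > 0:
            num += w * voxel_to_world(mask.grid, np.array(idx, float))
            den += w
    return num / den
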