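import numpy as np
import pytest

import fetalrecon as fr
from fetalrecon import experiments as ex

# desk-scale acquisition: the clinical geometry scaled by the ratio of the
# desk phantom voxel (1.75 mm) to the full-resolution voxel (0.7 mm)
DESK_ACQ = fr.AcquisitionSpec(in_plane_mm=1.75, slice_thickness_mm=3.5,
                              slice_spacing_mm=1.75, n_packages=1,
                              slice_order="ascending")


@pytest.fixture(scope="session")
def desk_phantom():
    """64³ phantom with the standard 112 mm field of view."""
    spec = fr.desk_spec(64)
    img, glob, organs = fr.make_phantom(spec)
    return spec, img, glob, organs


@pytest.fixture(scope="session")
def full_phantom():
    """Full-resolution 160³ / 0.7 mm phantom."""
    spec = fr.PhantomSpec()
    img, glob, organs = fr.make_phantom(spec)
    return spec, img, glob, organs


@pytest.fixture(scope="session")
def six_clean_stacks(desk_phantom):
    """Six motion-free desk-scale stacks in different slice orientations."""
    _, img, glob, organs = desk_phantom
    dirs = ex.stack_orientations()
    return [fr.simulate_stack(img, fr.RigidTransform.identity(), DESK_ACQ,
                              seed=i, labels=(glob, organs),
                              directions=dirs[i], name=f"s{i}")
            for i in range(6)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
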