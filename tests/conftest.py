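import numpy as np
import pytest

from acmap import synthetic as sy


@pytest.fixture(scope="session")
def scheme71():
    """The study acquisition: 61 directions at b=1500 plus 10 b=0 volumes."""
    return sy.make_gradient_scheme(61, 1500.0, 10, seed=1)


@pytest.fixture(scope="session")
def scheme_small():
    """A cheap scheme for pipeline tests: 30 directions, 4 b=0."""
    return sy.make_gradient_scheme(30, 1500.0, 4, seed=1)


@pytest.fixture(scope="session")
def tube_phantom(scheme_small):
    """Noise-free straight-tube phantom along x on a 16x8x8 grid, 2 mm."""
    tube = sy.Tube.straight((2, 6, 6), (30, 6, 6), radius=2.0)
    spec = sy.PhantomSpec(shape=(16, 8, 8), voxel_size=2.0, tubes=[tube], snr=np.inf)
    dwi, mask, gt, rois = sy.build_phantom(spec, seed=0, scheme=scheme_small)
    return {"dwi": dwi, "mask": mask, "gt": gt, "rois": rois, "scheme": scheme_small, "spec": spec}


@pytest.fixture(scope="session")
def noisy_tube_phantom(scheme_small):
    """Same geometry at the study SNR of 20."""
    tube = sy.Tube.straight((2, 6, 6), (30, 6, 6), radius=2.0)
    spec = sy.PhantomSpec(shape=(16, 8, 8), voxel_size=2.0, tubes=[tube], snr=20.0)
    dwi, mask, gt, rois = sy.build_phantom(spec, seed=3, scheme=scheme_small)
    return {"dwi": dwi, "mask": mask, "gt": gt, "rois": rois, "scheme": scheme_small, "spec": spec}
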