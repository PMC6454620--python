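import numpy as np
import pytest

from memseg3d.stack_io import IntensityStack
from memseg3d.synthetic_embryo import Phantom, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    """A fast 5-cell phantom (48x48x36 grid) for unit tests."""
    return generate_phantom(
        PhantomSpec(
            shape=(48, 48, 36),
            semi_axes=(19.0, 19.0, 14.0),
            n_cells=5,
            n_noise_blobs=2,
            noise_radius=(2.0, 3.0),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def clean_phantom() -> Phantom:
    """Blob-free attenuated phantom for normalization tests."""
    return generate_phantom(
        PhantomSpec(
            shape=(48, 48, 36),
            semi_axes=(19.0, 19.0, 14.0),
            n_cells=5,
            n_noise_blobs=0,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def plane_stack() -> tuple[IntensityStack, np.ndarray]:
    """A blurred bright plane at z=12 in a 32^3 grid, plus its true mask."""
    from scipy import ndimage as ndi

    vox = np.zeros((32, 32, 32))
    mask = np.zeros_like(vox, dtype=bool)
    mask[:, :, 12] = True
    vox[mask] = 100.0
    vox = ndi.gaussian_filter(vox, 1.0)
    return IntensityStack(vox), mask
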