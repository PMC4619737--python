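import numpy as np
import pytest

from mpirecon import (
    NoiseModel,
    PhantomSpec,
    PSFModel,
    ScanGeometry,
    make_phantom,
    native_image,
    simulate_partial_fovs,
)
from mpirecon.conditioning import default_fig_geometry


@pytest.fixture(scope="session")
def fig_geometry() -> ScanGeometry:
    """The reference 1D analysis geometry (p=20, s=15, N=18, n=105)."""
    return default_fig_geometry()


@pytest.fixture(scope="session")
def tiny_geometry() -> ScanGeometry:
    """n=5, p=3, d=1, N=3 — small enough to reason about by hand."""
    return ScanGeometry((5,), 3, 2, 3)


@pytest.fixture(scope="session")
def geometry_2d() -> ScanGeometry:
    return ScanGeometry((32, 105), 20, 15, 18, drive_axis=1)


@pytest.fixture(scope="session")
def native_2d(geometry_2d) -> np.ndarray:
    """Noise-free 2D native image with tracer-free drive-axis edges."""
    phantom = make_phantom(PhantomSpec(kind="random_blobs",
                                       shape=geometry_2d.image_shape, seed=5))
    return native_image(phantom, PSFModel(fwhm=4.0))


@pytest.fixture(scope="session")
def stack_2d(geometry_2d, native_2d) -> np.ndarray:
    return simulate_partial_fovs(native_2d, geometry_2d, dc_mode="remove")


@pytest.fixture(scope="session")
def native_1d(fig_geometry) -> np.ndarray:
    phantom = make_phantom(PhantomSpec(kind="random_blobs",
                                       shape=fig_geometry.image_shape, seed=3))
    return native_image(phantom, PSFModel(fwhm=4.0))
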