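import numpy as np
import pytest

from pctpath import Cylinder, ImagingGeometry, PhantomSpec, make_vessel_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def soft_tissue_geometry():
    """15 keV, 7 cm propagation, 6.5 um pixels, duality ratio 1000."""
    return ImagingGeometry(
        energy_keV=15.0, distance_m=0.07, pixel_m=6.5e-6, delta=1e-6, beta=1e-9
    )


@pytest.fixture
def axis_cylinder_phantom():
    """64^3 volume with one full-length axis-aligned cylinder, radius 8 voxels."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        voxel_size=6.5e-6,
        cylinders=(Cylinder((0.0, 32.0, 32.0), (1.0, 0.0, 0.0), 8.0, 200.0),),
        background_value=10.0,
    )
    volume, truth = make_vessel_phantom(spec)
    return spec, volume, truth


def gaussian_blob_thickness(n=256, peak_m=5e-4, sigma_px=40.0):
    yy, xx = np.mgrid[:n, :n]
    r2 = (yy - n / 2) ** 2 + (xx - n / 2) ** 2
    return peak_m * np.exp(-r2 / (2 * sigma_px**2))
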