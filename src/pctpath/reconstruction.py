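"""Parallel-beam filtered back-projection of sinograms into slices/volumes.

Synchrotron propagation-based setups place no optics between sample and
detector, so the beam is treated as parallel.  Filtering and
back-projection are delegated to scikit-image's ``iradon`` (frequency-
domain ramp filter, optionally windowed, linear-interpolation
back-projection scaled so attenuation units are recovered); this module
wraps it with the sinogram layout, center-offset handling and stacking
used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift
from skimage.transform import iradon

__all__ = ["Sinogram", "ReconVolume", "fbp_slice", "reconstruct_volume"]

_FILTERS = {"ramp": "ramp", "shepp-logan": "shepp-logan", "hann": "hann"}


@dataclass(frozen=True)
class Sinogram:
    """Per-slice parallel-beam line integrals.

    ``values`` is (n_angles, n_detector); ``angles`` are degrees in
    [0, 180), strictly increasing; ``pixel_m`` is the detector pitch.
    """

    values: np.ndarray
    angles: np.ndarray
    pixel_m: float = 6.5e-6

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        if values.ndim != 2 or values.shape[0] != angles.size:
            raise ValueError("values must be (n_angles, n_detector)")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing with no duplicates")
        if np.any((angles < 0) | (angles >= 180)):
            raise ValueError("angles must lie in [0, 180)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "angles", angles)


@dataclass(frozen=True)
class ReconVolume:
    """Reconstructed (z, y, x) attenuation volume with isotropic voxels."""

    voxels: np.ndarray
    voxel_size_m: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("reconstruction contains non-finite values")


def fbp_slice(
    sino: Sinogram,
    filter_name: str = "ramp",
    center_offset: float = 0.0,
) -> np.ndarray:
    """Filtered back-projection of one sinogram into a (y, x) slice.

    Parameters
    ----------
    sino : Sinogram
        Needs at least 2 angles.
    filter_name : {"ramp", "shepp-logan", "hann"}
        Frequency-domain window applied on top of the ramp.
    center_offset : float
        Rotation-axis offset from the detector center in pixels; the
        sinogram is shifted by -offset (linear interpolation) before
        back-projection.  Real acquisitions rarely center exactly.
    """
    if sino.angles.size < 2:
        raise ValueError("filtered back-projection needs at least 2 angles")
    if filter_name not in _FILTERS:
        raise ValueError(f"filter must be one of {sorted(_FILTERS)}, got {filter_name!r}")
    values = sino.values
    if center_offset:
        values = nd_shift(values, (0.0, -center_offset), order=1, mode="nearest")
    n_det = values.shape[1]
    return iradon(
        values.T,
        theta=sino.angles,
        filter_name=_FILTERS[filter_name],
        interpolation="linear",
        circle=True,
        output_size=n_det,
    )


def reconstruct_volume(
    sinogram_stack: np.ndarray,
    angles: np.ndarray,
    pixel_m: float = 6.5e-6,
    filter_name: str = "ramp",
    center_offset: float = 0.0,
) -> ReconVolume:
    """Reconstruct a (z, y, x) volume from a (z, n_angles, n_det) stack.

    Each slice is reconstructed with :func:`fbp_slice`; the voxel size
    equals the detector pixel size.
    """
    stack = np.asarray(sinogram_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("sinogram stack must be (z, n_angles, n_detector)")
    if stack.shape[0] == 0:
        raise ValueError("empty sinogram stack")
    angles = np.asarray(angles, dtype=float)
    if stack.shape[1] != angles.size:
        raise ValueError(
            f"angle count {angles.size} does not match sinogram shape {stack.shape}"
        )
    slices = [
        fbp_slice(Sinogram(s, angles, pixel_m), filter_name, center_offset)
        for s in stack
    ]
    return ReconVolume(voxels=np.stack(slices), voxel_size_m=pixel_m)
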