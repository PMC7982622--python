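"""Synthetic phantoms and forward physics for end-to-end pipeline testing.

No public image data exist for the tissue specimens this pipeline targets,
so every downstream stage is exercised on synthetic inputs with known
ground truth:

* 3D vessel-network phantoms (cylinders of known radius embedded in a
  uniform background) for segmentation and morphometry;
* labeled texture-class image sets (class-distinct correlation lengths and
  gray-level statistics) standing in for lesion-type image panels;
* Fresnel free-space-propagation projections of homogeneous objects for
  phase retrieval, and parallel-beam sinograms for reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import radon

from .geometry import ImagingGeometry

__all__ = [
    "Cylinder",
    "PhantomSpec",
    "make_vessel_phantom",
    "make_texture_dataset",
    "simulate_projection",
    "simulate_sinogram",
]


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder clipped to the grid: axis point, direction, radius.

    ``point`` and ``direction`` are (z, y, x) voxel coordinates; ``radius``
    is in voxels; ``value`` is the linear attenuation assigned inside.
    """

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if not np.any(np.asarray(self.direction, dtype=float)):
            raise ValueError("cylinder direction must be non-zero")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a deterministic cylinder-network phantom."""

    shape: tuple[int, int, int]
    voxel_size: float = 6.5e-6
    cylinders: tuple[Cylinder, ...] = ()
    background_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"phantom grid must be 3D with positive extents, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "cylinders", tuple(self.cylinders))


def make_vessel_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Rasterize a cylinder-network phantom and its ground truth.

    Voxels whose center lies within ``radius`` of a cylinder axis take that
    cylinder's value (later cylinders overwrite earlier ones on overlap);
    all others take ``background_value``.

    Returns
    -------
    volume : ndarray, shape ``spec.shape``
        float32 attenuation volume.
    truth : dict
        ``volume_fraction`` (exact voxel-count ratio of non-background),
        ``radii_voxels``, ``radii_m``, and ``n_cylinders``.
    """
    zz, yy, xx = np.meshgrid(
        np.arange(spec.shape[0], dtype=float),
        np.arange(spec.shape[1], dtype=float),
        np.arange(spec.shape[2], dtype=float),
        indexing="ij",
    )
    volume = np.full(spec.shape, spec.background_value, dtype=np.float32)
    inside_any = np.zeros(spec.shape, dtype=bool)
    for cyl in spec.cylinders:
        p = np.asarray(cyl.point, dtype=float)
        u = np.asarray(cyl.direction, dtype=float)
        u = u / np.linalg.norm(u)
        dz, dy, dx = zz - p[0], yy - p[1], xx - p[2]
        proj = dz * u[0] + dy * u[1] + dx * u[2]
        perp2 = (dz - proj * u[0]) ** 2 + (dy - proj * u[1]) ** 2 + (dx - proj * u[2]) ** 2
        inside = perp2 <= cyl.radius**2
        volume[inside] = cyl.value
        inside_any |= inside
    truth = {
        "volume_fraction": float(inside_any.sum() / inside_any.size),
        "radii_voxels": [c.radius for c in spec.cylinders],
        "radii_m": [c.radius * spec.voxel_size for c in spec.cylinders],
        "n_cylinders": len(spec.cylinders),
    }
    return volume, truth


def random_vessel_spec(
    shape: tuple[int, int, int],
    n_cylinders: int,
    radius_range: tuple[float, float] = (3.0, 12.0),
    value: float = 200.0,
    background_value: float = 10.0,
    seed: int = 0,
) -> PhantomSpec:
    """Draw a reproducible random cylinder network within the grid."""
    rng = np.random.default_rng(seed)
    cylinders = []
    for _ in range(n_cylinders):
        point = tuple(rng.uniform(0.25, 0.75) * np.asarray(shape, dtype=float))
        direction = tuple(rng.normal(size=3))
        radius = float(rng.uniform(*radius_range))
        cylinders.append(Cylinder(point, direction, radius, value))
    return PhantomSpec(shape=shape, cylinders=tuple(cylinders),
                       background_value=background_value, seed=seed)


def make_texture_dataset(
    n_classes: int,
    n_per_class: int,
    image_size: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labeled grayscale image set with class-distinct textures.

    Each class k gets its own spatial correlation length (Gaussian-filtered
    white noise, sigma growing with k), mean gray level and contrast, so
    texture statistics separate the classes while within-class variation
    remains.  Pixel values are clipped to [0, 255].

    Returns ``(images, labels)`` with ``images`` of shape
    ``(n_classes * n_per_class, image_size, image_size)`` (float64) and
    integer labels ``0 .. n_classes-1``, each appearing ``n_per_class``
    times.  Fully reproducible under ``seed``.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class <= 0 or image_size <= 0:
        raise ValueError("counts and image size must be positive")
    rng = np.random.default_rng(seed)
    images = np.empty((n_classes * n_per_class, image_size, image_size))
    labels = np.empty(n_classes * n_per_class, dtype=int)
    for k in range(n_classes):
        sigma = 0.8 + 0.6 * k               # correlation length, px
        mean = 60.0 + 140.0 * k / max(n_classes - 1, 1)
        spread = 18.0 + 4.0 * (k % 3)        # contrast differs across classes
        for j in range(n_per_class):
            idx = k * n_per_class + j
            noise = rng.normal(size=(image_size, image_size))
            field_ = gaussian_filter(noise, sigma, mode="wrap")
            field_ = (field_ - field_.mean()) / (field_.std() + 1e-12)
            images[idx] = np.clip(mean + spread * field_, 0.0, 255.0)
            labels[idx] = k
    return images, labels


def simulate_projection(
    thickness_map: np.ndarray,
    geom: ImagingGeometry,
    pad_factor: int = 2,
    fluence: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Fresnel free-space propagation image of a homogeneous object.

    The exit wave of a single-material object of projected thickness t is
    ``exp(-2*pi*beta*t/lambda) * exp(-2j*pi*delta*t/lambda)``.  It is
    propagated over distance D with the angular-spectrum transfer function
    ``H(u, v) = exp(-1j * pi * lambda * D * (u^2 + v^2))`` evaluated on the
    discrete frequency grid implied by the pixel pitch, on a grid
    zero-padded (edge-padded) by ``pad_factor`` to suppress wrap-around.
    Returns the squared modulus normalized to unit incident intensity.

    Parameters
    ----------
    thickness_map : 2D ndarray
        Projected thickness per pixel in metres, >= 0.
    geom : ImagingGeometry
        Must carry delta and beta.
    fluence : float, optional
        Incident photons per pixel; when given, Poisson noise at that level
        is applied (off by default) using ``seed``.
    """
    t = np.asarray(thickness_map, dtype=float)
    if t.ndim != 2:
        raise ValueError("thickness_map must be 2D")
    if np.any(t < 0):
        raise ValueError("projected thickness must be non-negative")
    delta, beta = geom.require_optical_constants()
    lam = geom.wavelength_m

    absorption = 2.0 * np.pi * beta * t / lam
    phase = -2.0 * np.pi * delta * t / lam
    psi = np.exp(-absorption + 1j * phase)

    if geom.distance_m > 0:
        ny, nx = psi.shape
        py, px = (pad_factor - 1) * ny // 2, (pad_factor - 1) * nx // 2
        psi_p = np.pad(psi, ((py, py), (px, px)), mode="edge")
        u = np.fft.fftfreq(psi_p.shape[1], d=geom.pixel_m)
        v = np.fft.fftfreq(psi_p.shape[0], d=geom.pixel_m)
        chi = np.pi * lam * geom.distance_m * (u[None, :] ** 2 + v[:, None] ** 2)
        psi_p = np.fft.ifft2(np.fft.fft2(psi_p) * np.exp(-1j * chi))
        psi = psi_p[py:py + ny, px:px + nx]

    intensity = np.abs(psi) ** 2
    if fluence is not None:
        if fluence <= 0:
            raise ValueError("fluence must be positive")
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(intensity * fluence).astype(float) / fluence
    return intensity


def simulate_sinogram(volume: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Parallel-beam line integrals (discrete Radon transform) per slice.

    Ray summation with linear interpolation over the inscribed circle of
    each (y, x) slice; line integrals are in units of attenuation-value
    per voxel path length (multiply by the voxel size for physical units).

    Parameters
    ----------
    volume : 2D or 3D ndarray
        A single slice or a (z, y, x) stack.
    angles : sequence of float
        Projection angles in degrees, each in [0, 180).

    Returns
    -------
    ndarray
        ``(n_angles, n_detector)`` for a slice, ``(z, n_angles, n_detector)``
        for a stack.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("angle list must be non-empty")
    if np.any((angles < 0) | (angles >= 180)):
        raise ValueError("angles must lie in [0, 180) degrees")
    vol = np.asarray(volume, dtype=float)

    def _one(sl: np.ndarray) -> np.ndarray:
        # restrict to the inscribed circle: parallel-beam FBP reconstructs
        # only this region, and rays outside it exit the detector row
        ny, nx = sl.shape
        yy, xx = np.ogrid[:ny, :nx]
        cy, cx = ny // 2, nx // 2  # rotation center of the discrete transform
        r = min(ny, nx) / 2.0
        masked = np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2, sl, 0.0)
        return radon(masked, theta=angles).T

    if vol.ndim == 2:
        return _one(vol)
    if vol.ndim == 3:
        return np.stack([_one(sl) for sl in vol])
    raise ValueError("volume must be 2D or 3D")
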