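"""Single-distance phase retrieval under the phase-attenuation duality.

For a homogeneous (single-material) weakly absorbing object imaged in the
near field at one sample-to-detector distance D, the object phase map can
be recovered from a single normalized projection I_D/I_in by a Fourier
filter.  With chi(u, v) = pi * lambda * D * (u^2 + v^2) on the discrete
frequency grid and epsilon = delta/beta, the retrieval implemented here is

    phi(x, y) = (epsilon / 2) * ln( F^-1 [ F(I_D / I_in)
                                          / (cos chi + epsilon * sin chi) ] )

which reduces, as chi -> 0, to the transport-of-intensity (Paganin-type)
low-pass filter 1 + epsilon * chi, and exactly inverts the linearized
homogeneous-object contrast transfer model used by the forward simulator.
At D = 0 the denominator is identically 1 and the formula degenerates to
the pure-absorption inversion phi = (epsilon/2) * ln(I).

The denominator crosses zero at finite frequencies, so a Tikhonov-style
magnitude clamp is applied; the pre-logarithm field is clipped to a small
positive floor and the number of clipped pixels is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import ImagingGeometry, wavelength_from_energy

__all__ = [
    "PhaseMap",
    "DoseParams",
    "wavelength_from_energy",
    "flat_dark_correct",
    "retrieve_phase",
    "estimate_dose",
]

#: lower bound applied to |cos chi + eps sin chi| before division
DEFAULT_REGULARIZATION = 1e-3
#: pre-log floor, as a fraction of the filtered-field maximum
PRELOG_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class PhaseMap:
    """Retrieved phase phi(x, y) in radians with its acquisition geometry."""

    phi: np.ndarray
    geom: ImagingGeometry
    n_clipped: int = 0  # pixels floored before the logarithm

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("retrieved phase must be finite everywhere")


@dataclass(frozen=True)
class DoseParams:
    """Inputs of the surface-dose estimate dose = F * E * (mu_en / rho).

    fluence_rate : photons / mm^2 / s
    energy_J     : photon energy in joules
    mu_en_over_rho : mass energy-absorption coefficient, mm^2 / kg
    exposure_s   : per-projection exposure time
    n_projections : projections per tomographic scan
    """

    fluence_rate: float
    energy_J: float
    mu_en_over_rho: float
    exposure_s: float
    n_projections: int = 1

    def __post_init__(self) -> None:
        for name in ("fluence_rate", "energy_J", "mu_en_over_rho", "exposure_s",
                     "n_projections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def flat_dark_correct(
    raw: np.ndarray,
    flat: np.ndarray,
    dark: np.ndarray | float = 0.0,
    floor: float = 1e-6,
) -> np.ndarray:
    """Background correction: (raw - dark) / (flat - dark), floored.

    ``flat`` and ``dark`` may be single frames or stacks; stacks are
    reduced by a per-pixel median (robust to hot pixels).  Pixels where
    flat <= dark are substituted with ``floor`` after a warning, and the
    normalized intensity is clipped below at ``floor`` so downstream
    logarithms stay finite.
    """
    raw = np.asarray(raw, dtype=float)
    flat = np.asarray(flat, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if flat.ndim == raw.ndim + 1:
        flat = np.median(flat, axis=0)
    if dark.ndim == raw.ndim + 1:
        dark = np.median(dark, axis=0)
    denom = flat - dark
    bad = denom <= 0
    if np.any(bad):
        warnings.warn(
            f"flat <= dark at {int(np.sum(bad))} pixel(s); substituting floor",
            RuntimeWarning,
            stacklevel=2,
        )
        denom = np.where(bad, 1.0, denom)
    out = (raw - dark) / denom
    out[np.broadcast_to(bad, out.shape)] = floor
    return np.clip(out, floor, None)


def duality_denominator(
    shape: tuple[int, int],
    geom: ImagingGeometry,
    variant: str = "duality",
) -> np.ndarray:
    """Fourier-domain denominator cos(chi) + eps*sin(chi) on the DFT grid.

    ``variant="alternative"`` selects the reading
    cos(chi) + (eps + chi)*sin(chi) of the same printed formula.
    """
    if geom.epsilon is None:
        raise ValueError("geometry must define epsilon = delta/beta")
    u = np.fft.fftfreq(shape[1], d=geom.pixel_m)
    v = np.fft.fftfreq(shape[0], d=geom.pixel_m)
    chi = np.pi * geom.wavelength_m * geom.distance_m * (
        u[None, :] ** 2 + v[:, None] ** 2
    )
    if variant == "duality":
        return np.cos(chi) + geom.epsilon * np.sin(chi)
    if variant == "alternative":
        return np.cos(chi) + (geom.epsilon + chi) * np.sin(chi)
    raise ValueError(f"unknown denominator variant {variant!r}")


def retrieve_phase(
    intensity: np.ndarray,
    geom: ImagingGeometry,
    regularization: float = DEFAULT_REGULARIZATION,
    denominator: str = "duality",
) -> PhaseMap:
    """Retrieve the phase map from one normalized near-field projection.

    Parameters
    ----------
    intensity : 2D ndarray
        Flat/dark-corrected intensity I_D / I_in, strictly positive.
    geom : ImagingGeometry
        Supplies wavelength, distance, pixel pitch and epsilon.
    regularization : float
        Minimum magnitude allowed for the Fourier denominator (Tikhonov
        clamp); must be positive.
    denominator : {"duality", "alternative"}
        Reading of the duality filter; see :func:`duality_denominator`.

    Returns
    -------
    PhaseMap
        phi in radians (negative for a phase-retarding object), plus the
        count of pixels floored before the logarithm.
    """
    img = np.asarray(intensity, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity must be a 2D projection")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if not np.all(img > 0):
        raise ValueError("intensity must be strictly positive (apply flat_dark_correct)")

    den = duality_denominator(img.shape, geom, variant=denominator)
    den = np.where(np.abs(den) < regularization,
                   regularization * np.where(den < 0, -1.0, 1.0), den)
    filtered = np.fft.ifft2(np.fft.fft2(img) / den).real

    floor = PRELOG_FLOOR_FRACTION * float(np.max(filtered))
    if floor <= 0:
        floor = PRELOG_FLOOR_FRACTION
    clipped = int(np.sum(filtered < floor))
    phi = 0.5 * geom.epsilon * np.log(np.clip(filtered, floor, None))
    return PhaseMap(phi=phi, geom=geom, n_clipped=clipped)


def estimate_dose(params: DoseParams) -> float:
    """Surface dose in Gy: fluence * exposure * n_proj * E * (mu_en/rho).

    With fluence_rate in photons/mm^2/s, energy in J and mu_en/rho in
    mm^2/kg the product resolves to J/kg = Gy.
    """
    return (
        params.fluence_rate
        * params.exposure_s
        * params.n_projections
        * params.energy_J
        * params.mu_en_over_rho
    )
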