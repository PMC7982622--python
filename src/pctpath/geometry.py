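"""Imaging geometry for propagation-based phase-contrast experiments.

A synchrotron propagation-based setup is fully described by the photon
energy (hence wavelength), the sample-to-detector distance D, the detector
pixel pitch, and the optical constants of the (assumed homogeneous) sample:
the refractive index is n = 1 - delta + i*beta, and the duality ratio
epsilon = delta/beta sets the strength of the single-distance phase
retrieval filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import scipy.constants as const


def wavelength_from_energy(energy_keV: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV.

    Uses lambda = h*c/E with CODATA constants; 15 keV gives 8.27e-11 m.

    Raises
    ------
    ValueError
        If ``energy_keV`` is not strictly positive.
    """
    if energy_keV <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_keV} keV")
    return const.h * const.c / (energy_keV * 1e3 * const.e)


@dataclass(frozen=True)
class ImagingGeometry:
    """Acquisition geometry and homogeneous-object optical constants.

    Parameters
    ----------
    energy_keV : float
        Photon energy in keV; the wavelength follows from lambda = hc/E.
    distance_m : float
        Sample-to-detector (propagation) distance D in metres, >= 0.
    pixel_m : float
        Detector pixel pitch in metres (defines the discrete frequency grid).
    delta, beta : float, optional
        Real-part decrement and imaginary part of the refractive index.
        Required for forward simulation; phase retrieval only needs epsilon.
    epsilon : float, optional
        Duality ratio delta/beta.  Derived from delta and beta when both are
        given; for soft tissue at 15 keV it is of order 1e2-1e3.
    """

    energy_keV: float
    distance_m: float
    pixel_m: float
    delta: float | None = None
    beta: float | None = None
    epsilon: float | None = None
    wavelength_m: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength_m", wavelength_from_energy(self.energy_keV))
        if self.distance_m < 0:
            raise ValueError("propagation distance must be >= 0")
        if self.pixel_m <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.epsilon is None and self.delta is not None and self.beta:
            object.__setattr__(self, "epsilon", self.delta / self.beta)
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon = delta/beta must be positive")

    def require_optical_constants(self) -> tuple[float, float]:
        """Return (delta, beta), raising if either is missing."""
        if self.delta is None or self.beta is None:
            raise ValueError("delta and beta are required for forward simulation")
        return self.delta, self.beta
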