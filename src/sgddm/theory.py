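"""Closed-form reference values for rigid-rod Brownian hydrodynamics.

Short cylindrical particles in a Newtonian fluid are well described by the
end-corrected rod expressions of Tirado and García de la Torre, which give
the orientationally averaged translational diffusion coefficient

    D_T = k_B T (ln p + nu_T) / (3 pi eta L),    nu_T = 0.312 + 0.565/p - 0.100/p^2

and the rotational diffusion coefficient about the short axes

    D_R = 3 k_B T (ln p + nu_R) / (pi eta L^3),  nu_R = -0.662 + 0.917/p - 0.050/p^2

with p = L/d the aspect ratio.  The end corrections are fitted for moderate
aspect ratios; below p ~ 2 they lose accuracy and a warning is emitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

#: Boltzmann constant, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

__all__ = [
    "RodGeometry",
    "rod_diffusion",
    "diffraction_limit",
    "celsius_to_kelvin",
    "BOLTZMANN_J_PER_K",
]


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from degrees Celsius to Kelvin."""
    return t_celsius + 273.15


@dataclass(frozen=True)
class RodGeometry:
    """Geometry and bath parameters of a rigid cylindrical particle.

    Parameters
    ----------
    length_nm : float
        Cylinder length L in nanometres.
    diameter_nm : float
        Cylinder diameter d in nanometres; must satisfy 0 < d < L.
    viscosity_mPas : float
        Dynamic viscosity of the suspending fluid in mPa·s (= cP).
    temperature_C : float
        Bath temperature in degrees Celsius.
    """

    length_nm: float
    diameter_nm: float
    viscosity_mPas: float = 1.0
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        if not (self.length_nm > self.diameter_nm > 0):
            raise ValueError("require length > diameter > 0")
        if self.viscosity_mPas <= 0:
            raise ValueError("viscosity must be positive")
        if not (-20.0 <= self.temperature_C <= 100.0):
            raise ValueError("temperature outside the liquid-water-like range")

    @property
    def aspect_ratio(self) -> float:
        return self.length_nm / self.diameter_nm


def rod_diffusion(geometry: RodGeometry) -> tuple[float, float]:
    """Translational and rotational diffusion coefficients of a rigid rod.

    Returns
    -------
    (D_T, D_R) : tuple of float
        Translational coefficient in µm²/s and rotational coefficient in 1/s,
        from the end-corrected cylinder (Tirado–García de la Torre) formulas.
    """
    p = geometry.aspect_ratio
    if p < 2.0:
        warnings.warn(
            f"aspect ratio p={p:.2f} < 2 is outside the validity range of the "
            "end-corrected rod expressions",
            stacklevel=2,
        )
    nu_t = 0.312 + 0.565 / p - 0.100 / p**2
    nu_r = -0.662 + 0.917 / p - 0.050 / p**2

    kT = BOLTZMANN_J_PER_K * celsius_to_kelvin(geometry.temperature_C)  # J
    eta = geometry.viscosity_mPas * 1e-3  # Pa·s
    L = geometry.length_nm * 1e-9  # m

    d_t_m2s = kT * (math.log(p) + nu_t) / (3.0 * math.pi * eta * L)
    d_r = 3.0 * kT * (math.log(p) + nu_r) / (math.pi * eta * L**3)
    return d_t_m2s * 1e12, d_r  # m²/s → µm²/s


def diffraction_limit(wavelength_um: float, numerical_aperture: float) -> float:
    """Smallest resolvable feature size λ/(2·NA) in µm."""
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if not (0 < numerical_aperture <= 1.5):
        raise ValueError("numerical aperture must be in (0, 1.5]")
    return wavelength_um / (2.0 * numerical_aperture)
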