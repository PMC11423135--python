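"""Photon-flux / irradiance conversion and shared physical constants.

Actinometry works in photon-flux units (einstein m^-2 s^-1, 1 E = 1 mol of
photons) while most optics literature reports irradiance in W m^-2.  For
monochromatic light of wavelength lambda the two are related by the molar
photon energy ``h * c * N_A / lambda``; the product ``h c N_A`` is close to
0.12 J m mol^-1, which gives the common shortcut

    I[W m^-2] ≈ 0.12 * I[E m^-2 s^-1] / lambda[m]

The package uses CODATA-precision constants internally; the rounded 0.12
shortcut is available through ``approximate=True`` for cross-checking
against hand calculations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as _const

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "HC_NA",
    "einstein_to_watt",
    "watt_to_einstein",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Planck constant, speed of light and Avogadro number (SI units)."""

    h: float = _const.Planck          # m^2 kg s^-1
    c: float = _const.speed_of_light  # m s^-1
    N_A: float = _const.Avogadro      # mol^-1

    @property
    def molar_photon_energy_factor(self) -> float:
        """h*c*N_A in J m mol^-1 (~0.1196; rounds to 0.12)."""
        return self.h * self.c * self.N_A


CONSTANTS = PhysicalConstants()

#: exact h*c*N_A (J m mol^-1)
HC_NA = CONSTANTS.molar_photon_energy_factor

#: rounded shortcut constant used in quick hand conversions
HC_NA_APPROX = 0.12


def _check_wavelength(wavelength_nm: float) -> float:
    wl = float(wavelength_nm)
    if not np.isfinite(wl) or wl <= 0:
        raise ValueError(f"wavelength must be positive and finite, got {wavelength_nm!r}")
    return wl


def einstein_to_watt(photon_flux, wavelength_nm, *, approximate: bool = False):
    """Convert photon flux (E m^-2 s^-1) to irradiance (W m^-2).

    Parameters
    ----------
    photon_flux : float or array_like
        Photon flux density in einstein m^-2 s^-1 (nonnegative).
    wavelength_nm : float
        Wavelength of the (monochromatic) light in nm.
    approximate : bool
        Use the rounded 0.12 J m mol^-1 shortcut instead of exact constants.

    Returns
    -------
    float or ndarray
        Irradiance in W m^-2.
    """
    wl_m = _check_wavelength(wavelength_nm) * 1e-9
    flux = np.asarray(photon_flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("photon flux must be nonnegative")
    factor = HC_NA_APPROX if approximate else HC_NA
    out = factor / wl_m * flux
    return float(out) if np.isscalar(photon_flux) or out.ndim == 0 else out


def watt_to_einstein(irradiance, wavelength_nm, *, approximate: bool = False):
    """Convert irradiance (W m^-2) to photon flux (E m^-2 s^-1).

    Exact inverse of :func:`einstein_to_watt` for the same ``approximate``
    setting.
    """
    wl_m = _check_wavelength(wavelength_nm) * 1e-9
    irr = np.asarray(irradiance, dtype=float)
    if np.any(irr < 0):
        raise ValueError("irradiance must be nonnegative")
    factor = HC_NA_APPROX if approximate else HC_NA
    out = irr * wl_m / factor
    return float(out) if np.isscalar(irradiance) or out.ndim == 0 else out
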