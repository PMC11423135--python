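"""Scaling a broadband source spectrum from one measured rise time.

For polychromatic light with spectral photon flux I(lambda) the
photoactivation rate integrates the action spectrum:

    1/tau = integral sigma(lambda) I(lambda) dlambda
          = S_I * integral sigma(lambda) j(lambda) dlambda = S_I * AS

where j(lambda) = I(lambda)/S_I is the emission spectrum normalized to unit
integral and S_I the total photon flux (E m^-2 s^-1).  Given an unscaled
emission spectrum S(lambda) of the source (arbitrary units) and one
measured tau, the absolute spectral photon flux follows as
``I(lambda) = S_I * j(lambda)`` with ``S_I = 1/(tau * AS)``.

Emission outside the validated action range of sigma (400-650 nm) cannot
contribute to the measured rate in a calibrated way; it is excluded from
AS, and S_I then refers to the in-range photon flux.  The fraction of the
raw spectrum falling outside the range is reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import CrossSectionSpectrum, default_cross_section_spectrum

__all__ = [
    "EmissionSpectrum",
    "ScaledSpectralIntensity",
    "read_emission_csv",
    "normalize_spectrum",
    "action_spectrum_integral",
    "scale_source",
]

#: emission above this wavelength overlaps the ChlF detection band
OVERLAP_LIMIT_NM = 665.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """Source emission spectrum on a wavelength grid.

    ``values`` are arbitrary units for a raw spectrum, or nm^-1 once
    normalized to unit trapezoidal integral (``normalized`` True).
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.size != v.size or wl.size < 3:
            raise ValueError("need matching grids with at least 3 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectrum values must be nonnegative")
        if self.normalized:
            integral = float(np.trapezoid(v, wl))
            if abs(integral - 1.0) > 1e-9:
                raise ValueError(
                    f"normalized spectrum must integrate to 1, got {integral!r}"
                )

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.wavelength_nm))


def read_emission_csv(path) -> EmissionSpectrum:
    """Load a raw emission spectrum CSV (columns wavelength_nm, value)."""
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"} <= set(df.columns):
        raise ValueError("emission CSV needs 'wavelength_nm' and 'value' columns")
    df = df.sort_values("wavelength_nm")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(dtype=float),
                            df["value"].to_numpy(dtype=float))


def normalize_spectrum(raw: EmissionSpectrum) -> EmissionSpectrum:
    """j(lambda) = S(lambda)/S with S the trapezoidal integral of S(lambda)."""
    S = raw.integral
    if S <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return EmissionSpectrum(raw.wavelength_nm, raw.values / S, normalized=True)


def _overlap_grid(spectrum: CrossSectionSpectrum, j: EmissionSpectrum):
    lo = max(spectrum.valid_range_nm[0], j.wavelength_nm[0])
    hi = min(spectrum.valid_range_nm[1], j.wavelength_nm[-1])
    if not (hi > lo):
        raise ValueError(
            "no overlap between the emission spectrum and the validated "
            f"action range [{spectrum.valid_range_nm[0]:g}, "
            f"{spectrum.valid_range_nm[1]:g}] nm"
        )
    grid = np.union1d(spectrum.wavelength_nm, j.wavelength_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    for edge in (lo, hi):
        if not np.isclose(grid, edge).any():
            grid = np.sort(np.append(grid, edge))
    return grid


def action_spectrum_integral(
    sigma_spectrum: CrossSectionSpectrum, j: EmissionSpectrum
) -> float:
    """AS = integral of sigma(lambda) j(lambda) dlambda (m^2 mol^-1).

    Both factors are linearly interpolated onto the union grid of the
    overlap between the emission support and sigma's validity range, and
    integrated with the trapezoid rule.  When part of the emission falls
    outside the action range, j is renormalized over the overlap so that
    AS remains the mean cross-section seen by the in-range photons.
    """
    if not j.normalized:
        j = normalize_spectrum(j)
    grid = _overlap_grid(sigma_spectrum, j)
    sig = np.interp(grid, sigma_spectrum.wavelength_nm, sigma_spectrum.sigma)
    jj = np.interp(grid, j.wavelength_nm, j.values)
    in_range = float(np.trapezoid(jj, grid))
    if in_range <= 0:
        raise ValueError("emission spectrum carries no weight inside the action range")
    return float(np.trapezoid(sig * jj, grid)) / in_range


def in_range_fraction(sigma_spectrum: CrossSectionSpectrum, j: EmissionSpectrum) -> float:
    """Fraction of the emission integral inside sigma's validity range."""
    if not j.normalized:
        j = normalize_spectrum(j)
    grid = _overlap_grid(sigma_spectrum, j)
    jj = np.interp(grid, j.wavelength_nm, j.values)
    return float(np.trapezoid(jj, grid))


@dataclass(frozen=True)
class ScaledSpectralIntensity:
    """Absolute spectral photon flux of the source, from one tau."""

    S_I: float                     # total in-range photon flux, E m^-2 s^-1
    action_integral: float         # AS, m^2 mol^-1
    wavelength_nm: np.ndarray      # overlap grid
    I_lambda: np.ndarray           # S_I * j(lambda), E m^-2 s^-1 nm^-1
    tau_used: float
    fraction_in_range: float = 1.0
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "S_I_E_m2_s": self.S_I,
            "action_integral_m2_mol": self.action_integral,
            "tau_s": self.tau_used,
            "fraction_in_action_range": self.fraction_in_range,
            "warnings": list(self.warnings),
            "spectral_intensity": {
                "wavelength_nm": self.wavelength_nm.tolist(),
                "I_lambda_E_m2_s_nm": self.I_lambda.tolist(),
            },
        }


def scale_source(
    tau_s: float,
    sigma_spectrum: CrossSectionSpectrum | None,
    raw_spectrum: EmissionSpectrum,
) -> ScaledSpectralIntensity:
    """Scale a raw emission spectrum to absolute photon flux via S_I = 1/(tau AS)."""
    if not (tau_s > 0) or not np.isfinite(tau_s):
        raise ValueError(f"tau must be positive and finite, got {tau_s!r}")
    sigma_spectrum = sigma_spectrum or default_cross_section_spectrum()
    j = raw_spectrum if raw_spectrum.normalized else normalize_spectrum(raw_spectrum)
    AS = action_spectrum_integral(sigma_spectrum, j)
    if not (AS > 0):
        raise ValueError("action-spectrum integral must be positive")
    S_I = 1.0 / (tau_s * AS)

    warnings: list[str] = []
    if raw_spectrum.wavelength_nm[-1] > OVERLAP_LIMIT_NM:
        warnings.append("emission_overlap")
    frac = in_range_fraction(sigma_spectrum, j)
    if frac < 1.0 - 1e-9:
        warnings.append("emission_outside_action_range")

    grid = _overlap_grid(sigma_spectrum, j)
    jj = np.interp(grid, j.wavelength_nm, j.values) / frac
    return ScaledSpectralIntensity(
        S_I=S_I, action_integral=AS, wavelength_nm=grid, I_lambda=S_I * jj,
        tau_used=tau_s, fraction_in_range=frac, warnings=tuple(warnings),
    )
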