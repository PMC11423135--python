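"""Wavelength-dependent photoactivation cross-section and intensity retrieval.

The photoactivation cross-section sigma(lambda) of the photosynthetic
apparatus is proportional to its fluorescence excitation spectrum (the
quantum yield of the initial step is assumed wavelength-independent), so a
normalized excitation coefficient eps_norm(lambda) — fixed to 1 at 470 nm —
anchored by a single reference value sigma(470) yields sigma at any
wavelength within the 400-650 nm action range:

    sigma(lambda) = eps_norm(lambda) * sigma_470

With sigma known, a measured characteristic time tau converts to incident
photon flux through ``I = 1/(sigma * tau)``.  Because the leaf-to-leaf
dispersion of sigma is large (roughly a factor two), the estimate carries a
factor-two interval.

The packaged default spectrum is a synthetic reconstruction: a
piecewise-linear interpolation through the four tabulated anchors
(eps_norm = 1.0, 1.0, 0.2, 0.4 at 405, 470, 550, 630 nm) with the average
anchor sigma(470) = 1.1e6 m^2 mol^-1.  Users with a full measured
excitation spectrum should load it with
:func:`build_spectrum_from_excitation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import einstein_to_watt

__all__ = [
    "SIGMA_470_DEFAULT",
    "TABLE_ANCHORS",
    "I_SUP_DEFAULT",
    "CrossSectionSpectrum",
    "IntensityEstimate",
    "default_cross_section_spectrum",
    "build_spectrum_from_excitation",
    "sigma_at",
    "retrieve_intensity",
]

#: species-averaged cross-section at 470 nm (m^2 mol^-1)
SIGMA_470_DEFAULT = 1.1e6

#: (wavelength nm, eps_norm) anchors of the normalized excitation coefficient
TABLE_ANCHORS = ((405.0, 1.0), (470.0, 1.0), (550.0, 0.2), (630.0, 0.4))

#: upper photon flux validated for a reliable measurement (E m^-2 s^-1)
I_SUP_DEFAULT = 1.0e-2

VALID_RANGE_NM = (400.0, 650.0)


@dataclass(frozen=True)
class CrossSectionSpectrum:
    """sigma(lambda) on a wavelength grid, anchored at a reference value.

    ``sigma = eps_norm * anchor_sigma`` holds on the grid, with
    ``eps_norm`` the excitation coefficient normalized to 1 at the anchor
    wavelength (470 nm by default).
    """

    wavelength_nm: np.ndarray
    eps_norm: np.ndarray
    anchor_sigma: float = SIGMA_470_DEFAULT
    anchor_wavelength_nm: float = 470.0
    valid_range_nm: tuple[float, float] = VALID_RANGE_NM
    i_sup: float = I_SUP_DEFAULT

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        eps = np.asarray(self.eps_norm, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "eps_norm", eps)
        if wl.size != eps.size or wl.size < 2:
            raise ValueError("need matching wavelength/eps grids with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(eps <= 0):
            raise ValueError("eps_norm must be positive on the grid")
        if not (self.anchor_sigma > 0):
            raise ValueError("anchor sigma must be positive")

    @property
    def sigma(self) -> np.ndarray:
        """sigma(lambda) on the grid (m^2 mol^-1)."""
        return self.eps_norm * self.anchor_sigma

    def __call__(self, wavelength_nm) -> float | np.ndarray:
        return sigma_at(self, wavelength_nm)

    def eps_at(self, wavelength_nm):
        """Linear interpolation of eps_norm (validity range enforced)."""
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.valid_range_nm
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"wavelength outside the validated action range "
                f"[{lo:g}, {hi:g}] nm: {wavelength_nm!r}"
            )
        out = np.interp(wl, self.wavelength_nm, self.eps_norm)
        return float(out) if out.ndim == 0 else out


def sigma_at(spectrum: CrossSectionSpectrum, wavelength_nm):
    """sigma(lambda) in m^2 mol^-1 by linear interpolation on the grid."""
    eps = spectrum.eps_at(wavelength_nm)
    return eps * spectrum.anchor_sigma


def default_cross_section_spectrum(
    anchor_sigma: float = SIGMA_470_DEFAULT,
) -> CrossSectionSpectrum:
    """Packaged default sigma(lambda): synthetic 4-anchor reconstruction.

    Piecewise-linear through the tabulated eps_norm anchors at 405, 470,
    550 and 630 nm, held constant from 400 to 405 nm and from 630 to
    650 nm.  This is an approximation of the full averaged excitation
    spectrum, which is not tabulated here.
    """
    wl = np.array([VALID_RANGE_NM[0]] + [a[0] for a in TABLE_ANCHORS]
                  + [VALID_RANGE_NM[1]])
    eps = np.array([TABLE_ANCHORS[0][1]] + [a[1] for a in TABLE_ANCHORS]
                   + [TABLE_ANCHORS[-1][1]])
    return CrossSectionSpectrum(wavelength_nm=wl, eps_norm=eps,
                                anchor_sigma=anchor_sigma)


def build_spectrum_from_excitation(
    excitation,
    anchor_wavelength_nm: float = 470.0,
    anchor_sigma: float = SIGMA_470_DEFAULT,
    smooth_window: int = 1,
) -> CrossSectionSpectrum:
    """Build sigma(lambda) from a measured fluorescence excitation spectrum.

    Parameters
    ----------
    excitation : path or DataFrame or (wavelength_nm, value) arrays
        Excitation spectrum; CSV files need ``wavelength_nm`` and ``value``
        columns.
    anchor_wavelength_nm : float
        Wavelength at which the spectrum is normalized to 1.
    anchor_sigma : float
        Cross-section value assigned at the anchor (m^2 mol^-1).
    smooth_window : int
        Centred moving-average window applied to the raw spectrum.
    """
    if isinstance(excitation, (tuple, list)) and len(excitation) == 2:
        wl = np.asarray(excitation[0], dtype=float)
        val = np.asarray(excitation[1], dtype=float)
    else:
        df = excitation if isinstance(excitation, pd.DataFrame) else pd.read_csv(excitation)
        if not {"wavelength_nm", "value"} <= set(df.columns):
            raise ValueError("excitation CSV needs 'wavelength_nm' and 'value' columns")
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        val = df["value"].to_numpy(dtype=float)
    order = np.argsort(wl)
    wl, val = wl[order], val[order]
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        val = np.convolve(val, kernel, "same") / np.convolve(np.ones_like(val), kernel, "same")
    if not (wl[0] <= anchor_wavelength_nm <= wl[-1]):
        raise ValueError(
            f"anchor wavelength {anchor_wavelength_nm} nm outside the spectrum "
            f"support [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    lo = max(VALID_RANGE_NM[0], wl[0])
    hi = min(VALID_RANGE_NM[1], wl[-1])
    keep = (wl >= lo) & (wl <= hi)
    wl, val = wl[keep], val[keep]
    if np.any(val <= 0):
        raise ValueError("excitation spectrum must be positive within 400-650 nm")
    anchor_val = float(np.interp(anchor_wavelength_nm, wl, val))
    eps = val / anchor_val
    return CrossSectionSpectrum(
        wavelength_nm=wl, eps_norm=eps, anchor_sigma=anchor_sigma,
        anchor_wavelength_nm=anchor_wavelength_nm,
        valid_range_nm=(float(wl[0]), float(wl[-1])),
    )


@dataclass(frozen=True)
class IntensityEstimate:
    """Light intensity retrieved from a fitted tau via I = 1/(sigma tau)."""

    intensity: float              # E m^-2 s^-1
    intensity_w: float            # W m^-2
    lower: float                  # intensity / 2
    upper: float                  # 2 * intensity
    wavelength_nm: float | None
    sigma_used: float
    tau_used: float
    qc_pass: bool = True
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "intensity_E_m2_s": self.intensity,
            "intensity_W_m2": self.intensity_w,
            "interval_E_m2_s": [self.lower, self.upper],
            "wavelength_nm": self.wavelength_nm,
            "sigma_m2_mol": self.sigma_used,
            "tau_s": self.tau_used,
            "qc_pass": self.qc_pass,
            "warnings": list(self.warnings),
        }


def retrieve_intensity(
    tau_s: float,
    wavelength_nm: float | None = None,
    spectrum: CrossSectionSpectrum | None = None,
    sigma_override: float | None = None,
    qc_ratio: float | None = None,
    qc_threshold: float = 0.75,
) -> IntensityEstimate:
    """Convert a characteristic time into incident photon flux.

    ``I = 1/(sigma * tau)`` with sigma either given directly
    (``sigma_override``) or interpolated from the cross-section spectrum at
    ``wavelength_nm``.  The result carries a factor-two interval (the
    leaf-to-leaf dispersion of sigma), a QC flag, and a warning when the
    estimate exceeds the validated intensity range.
    """
    if not (tau_s > 0) or not np.isfinite(tau_s):
        raise ValueError(f"tau must be positive and finite, got {tau_s!r}")
    warnings: list[str] = []
    if sigma_override is not None:
        sigma = float(sigma_override)
    else:
        if wavelength_nm is None:
            raise ValueError("need wavelength_nm or sigma_override to resolve sigma")
        spectrum = spectrum or default_cross_section_spectrum()
        sigma = float(sigma_at(spectrum, wavelength_nm))
    if sigma <= 0:
        raise ValueError("cross-section must be positive")
    intensity = 1.0 / (sigma * tau_s)
    i_sup = spectrum.i_sup if spectrum is not None else I_SUP_DEFAULT
    if intensity > i_sup:
        warnings.append("outside_validated_range")
    qc_pass = True
    if qc_ratio is not None and qc_ratio < qc_threshold:
        qc_pass = False
        warnings.append(
            f"qc_ratio {qc_ratio:.3f} below {qc_threshold:g}: retrieval unreliable"
        )
    intensity_w = (
        einstein_to_watt(intensity, wavelength_nm) if wavelength_nm else float("nan")
    )
    return IntensityEstimate(
        intensity=intensity, intensity_w=intensity_w,
        lower=intensity / 2.0, upper=2.0 * intensity,
        wavelength_nm=wavelength_nm, sigma_used=sigma, tau_used=tau_s,
        qc_pass=qc_pass, warnings=tuple(warnings),
    )
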