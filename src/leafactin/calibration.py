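"""Cross-section calibration from paired (intensity, 1/tau) measurements.

In the light-limited regime the photoactivation rate is linear in the
photon flux, ``1/tau = sigma * I + k`` (the intercept k collects the back
reaction and downstream electron transfer), so sigma is the slope of an
ordinary least-squares regression of 1/tau on I.  The protocol measures at
least seven intensity levels, discards points whose fluorescence QC ratio
(F_m - F_0)/F_m falls below 0.75, performs a first fit, removes residual
outliers at |z| > 2 (at most two per series), and refits once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .units import watt_to_einstein

__all__ = [
    "CalibrationError",
    "CalibrationPoint",
    "CalibrationResult",
    "CrossSectionCalibrator",
    "fit_sigma",
    "aggregate_sigma",
]

logger = logging.getLogger(__name__)

MIN_POINTS = 5
RECOMMENDED_POINTS = 7
MAX_REMOVALS = 2


class CalibrationError(RuntimeError):
    """Raised when a calibration series cannot yield a cross-section."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (photon flux, photoactivation rate) pair of a series.

    ``intensity`` in E m^-2 s^-1 (use ``from_watt`` for W m^-2 inputs),
    ``rate`` = 1/tau in s^-1.
    """

    intensity: float
    rate: float
    qc_ratio: float = float("nan")
    qc_pass: bool = True
    label: str = ""

    def __post_init__(self):
        if not (self.intensity > 0):
            raise ValueError(f"intensity must be positive, got {self.intensity}")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")

    @classmethod
    def from_watt(cls, irradiance_w: float, rate: float, wavelength_nm: float,
                  **kw) -> "CalibrationPoint":
        return cls(intensity=watt_to_einstein(irradiance_w, wavelength_nm),
                   rate=rate, **kw)


@dataclass(frozen=True)
class CalibrationResult:
    """Slope/intercept of the 1/tau-vs-I regression with bookkeeping."""

    sigma: float                  # slope, m^2 mol^-1
    sigma_sd: float               # OLS standard deviation of the slope
    intercept: float              # s^-1 (0 when fitted through the origin)
    intercept_sd: float
    n_used: int
    r_squared: float
    removed_points: tuple[tuple[int, str], ...] = ()  # (index, reason)
    through_origin: bool = False

    def to_dict(self) -> dict:
        return {
            "sigma_m2_mol": self.sigma,
            "sigma_sd_m2_mol": self.sigma_sd,
            "intercept_s": self.intercept,
            "intercept_sd_s": self.intercept_sd,
            "n_used": self.n_used,
            "r_squared": self.r_squared,
            "removed_points": [list(r) for r in self.removed_points],
            "through_origin": self.through_origin,
        }


def _ols(I: np.ndarray, rate: np.ndarray, through_origin: bool):
    X = I[:, None] if through_origin else sm.add_constant(I)
    return sm.OLS(rate, X).fit()


class CrossSectionCalibrator(BaseEstimator, RegressorMixin):
    """OLS estimator of sigma with the two-pass z-score outlier rejection.

    scikit-learn style: ``fit(X, y)`` with ``X`` the photon fluxes
    (E m^-2 s^-1, shape (n,) or (n, 1)) and ``y`` the rates 1/tau (s^-1).
    Fitted attributes: ``sigma_`` (slope), ``sigma_sd_``, ``intercept_``,
    ``removed_`` and ``result_``.

    Parameters
    ----------
    z_threshold : float
        Studentized-residual threshold of the outlier pass (default 2.0).
    through_origin : bool
        Force the regression through the origin (strict proportionality
        1/tau = sigma I); by default an intercept is included, since the
        two-state kinetics predicts 1/tau = sigma I + k.
    max_removals : int
        Outliers removed at most per series (default 2).
    """

    def __init__(self, z_threshold: float = 2.0, through_origin: bool = False,
                 max_removals: int = MAX_REMOVALS):
        self.z_threshold = z_threshold
        self.through_origin = through_origin
        self.max_removals = max_removals

    def fit(self, X, y):
        I = np.asarray(X, dtype=float).reshape(-1)
        rate = np.asarray(y, dtype=float).reshape(-1)
        if I.size != rate.size:
            raise ValueError("X and y must have equal length")
        if I.size < MIN_POINTS:
            raise CalibrationError(
                f"need at least {MIN_POINTS} usable points, got {I.size}"
            )
        if I.size < RECOMMENDED_POINTS:
            logger.warning(
                "only %d intensity levels; %d or more are recommended",
                I.size, RECOMMENDED_POINTS,
            )

        first = _ols(I, rate, self.through_origin)
        infl_sd = np.sqrt(max(first.mse_resid, 1e-300))
        z = first.resid / infl_sd
        # internally studentized residuals where leverage is available
        try:
            z = first.get_influence().resid_studentized_internal
        except Exception:
            pass
        order = np.argsort(-np.abs(z))
        removed = [int(i) for i in order[: self.max_removals]
                   if np.abs(z[i]) > self.z_threshold]
        keep = np.ones(I.size, dtype=bool)
        keep[removed] = False
        if keep.sum() < MIN_POINTS:
            raise CalibrationError(
                "outlier rejection left fewer than the minimum usable points"
            )
        final = _ols(I[keep], rate[keep], self.through_origin)

        if self.through_origin:
            slope, slope_sd = float(final.params[0]), float(final.bse[0])
            intercept = intercept_sd = 0.0
        else:
            intercept, slope = (float(v) for v in final.params)
            intercept_sd, slope_sd = (float(v) for v in final.bse)
        if slope <= 0:
            raise CalibrationError(
                "non-photochemical regime: fitted slope is not positive"
            )

        cond = np.linalg.cond(np.c_[np.ones(keep.sum()), I[keep]])
        if cond > 1e8:
            logger.warning("ill-conditioned calibration design (cond=%.2g)", cond)

        self.sigma_ = slope
        self.sigma_sd_ = slope_sd
        self.intercept_ = intercept
        self.intercept_sd_ = intercept_sd
        self.removed_ = tuple((i, "z_outlier") for i in sorted(removed))
        self.result_ = CalibrationResult(
            sigma=slope, sigma_sd=slope_sd, intercept=intercept,
            intercept_sd=intercept_sd, n_used=int(keep.sum()),
            r_squared=float(final.rsquared), removed_points=self.removed_,
            through_origin=self.through_origin,
        )
        return self

    def predict(self, X):
        I = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.sigma_ * I


def fit_sigma(
    points,
    z_threshold: float = 2.0,
    through_origin: bool = False,
    qc_threshold: float = 0.75,
) -> CalibrationResult:
    """Calibrate sigma from a list of :class:`CalibrationPoint`.

    QC-failed points (``qc_pass`` False, or ``qc_ratio`` below the
    threshold) are removed first with reason ``qc_fail``; the z-score
    outlier pass then runs on the remainder.  Removed-point indices refer
    to the input list.
    """
    points = list(points)
    qc_removed = []
    usable_idx = []
    for i, p in enumerate(points):
        bad_ratio = np.isfinite(p.qc_ratio) and p.qc_ratio < qc_threshold
        if (not p.qc_pass) or bad_ratio:
            qc_removed.append((i, "qc_fail"))
        else:
            usable_idx.append(i)
    if len(usable_idx) < MIN_POINTS:
        raise CalibrationError(
            f"only {len(usable_idx)} QC-passing points; need {MIN_POINTS}"
        )
    I = np.array([points[i].intensity for i in usable_idx])
    rate = np.array([points[i].rate for i in usable_idx])
    est = CrossSectionCalibrator(z_threshold=z_threshold,
                                 through_origin=through_origin).fit(I, rate)
    removed = tuple(qc_removed) + tuple(
        (usable_idx[i], reason) for i, reason in est.removed_
    )
    r = est.result_
    return CalibrationResult(
        sigma=r.sigma, sigma_sd=r.sigma_sd, intercept=r.intercept,
        intercept_sd=r.intercept_sd, n_used=r.n_used, r_squared=r.r_squared,
        removed_points=tuple(sorted(removed)), through_origin=through_origin,
    )


def aggregate_sigma(results, bins: int = 10):
    """Mean, SD and histogram of per-leaf sigma values.

    Accepts :class:`CalibrationResult` objects or raw sigma floats; needs
    at least two entries.  Returns ``(mean, sd, (hist_counts, bin_edges))``
    with the SD the population-style sample standard deviation (ddof=1).
    """
    sigmas = np.array([
        r.sigma if isinstance(r, CalibrationResult) else float(r) for r in results
    ])
    if sigmas.size < 2:
        raise ValueError("need at least 2 calibration results to aggregate")
    mean = float(sigmas.mean())
    sd = float(sigmas.std(ddof=1))
    hist = np.histogram(sigmas, bins=bins)
    return mean, sd, hist
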