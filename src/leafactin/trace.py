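"""Fluorescence-trace container, CSV I/O and pre-fit conditioning.

A measurement is a chlorophyll-fluorescence signal recorded versus time at
a high acquisition rate (up to a few MHz), starting ~10 ms before the
illumination is switched on so that a dark baseline is available.  Before
fitting, the trace is onset-aligned, truncated at the fluorescence maximum,
smoothed with a centred moving average, and logarithmically subsampled so
that every decade of time carries comparable weight in the least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraceError",
    "FluorescenceTrace",
    "OnsetResult",
    "read_trace_csv",
    "detect_onset",
    "moving_average",
    "log_subsample",
    "truncate_at_max",
]

logger = logging.getLogger(__name__)

MIN_TRACE_LENGTH = 50


class TraceError(ValueError):
    """Raised when a trace cannot be loaded or violates its contract."""


@dataclass
class FluorescenceTrace:
    """Time-stamped chlorophyll-fluorescence signal.

    Attributes
    ----------
    time_s : ndarray
        Strictly increasing time stamps in seconds.  By convention the
        illumination onset is at t = 0 once the trace has been aligned
        (pre-onset baseline samples then carry negative times).
    signal : ndarray
        Fluorescence signal, arbitrary units, same length as ``time_s``.
    wavelength_nm : float or None
        Excitation wavelength of the actinic light.
    rate_hz : float or None
        Nominal acquisition rate; inferred from the time axis when absent.
    rise_time_s : float or None
        Instrument (light source / detector) rise time, used by the
        instrument-limited guard of the fit pipeline.
    """

    time_s: np.ndarray
    signal: np.ndarray
    wavelength_nm: float | None = None
    rate_hz: float | None = None
    rise_time_s: float | None = None
    meta: dict = field(default_factory=dict)
    # derived traces (smoothed/subsampled/truncated) may legitimately be
    # shorter than the raw-acquisition minimum
    min_length: int = MIN_TRACE_LENGTH

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.ndim != 1 or self.signal.ndim != 1:
            raise TraceError("time and signal must be 1-D arrays")
        if self.time_s.size != self.signal.size:
            raise TraceError("time and signal must have equal length")
        if self.time_s.size < self.min_length:
            raise TraceError(
                f"trace too short: {self.time_s.size} samples < {self.min_length}"
            )
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.signal))):
            raise TraceError("trace contains non-finite values")
        if np.any(np.diff(self.time_s) <= 0):
            raise TraceError("time not strictly increasing")
        if self.rate_hz is None:
            self.rate_hz = float(1.0 / np.median(np.diff(self.time_s)))

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def with_data(self, time_s: np.ndarray, signal: np.ndarray) -> "FluorescenceTrace":
        """New trace with the same metadata but different samples."""
        return FluorescenceTrace(
            time_s=np.asarray(time_s, dtype=float),
            signal=np.asarray(signal, dtype=float),
            wavelength_nm=self.wavelength_nm,
            rate_hz=self.rate_hz,
            rise_time_s=self.rise_time_s,
            meta=dict(self.meta),
            min_length=2,
        )


@dataclass(frozen=True)
class OnsetResult:
    """Detected illumination onset of a trace."""

    onset_index: int
    onset_time_s: float
    F0_estimate: float
    baseline_sd: float
    baseline_mean: float = 0.0
    no_baseline: bool = False


def read_trace_csv(
    path,
    time_column: str = "time_s",
    signal_column: str = "signal",
    delimiter: str = ",",
    wavelength_nm: float | None = None,
    rise_time_s: float | None = None,
) -> FluorescenceTrace:
    """Load a fluorescence trace from a two-column CSV file.

    Rows with non-finite time or signal are dropped (a count is logged);
    the remaining trace must satisfy the ``FluorescenceTrace`` contract.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    for col in (time_column, signal_column):
        if col not in df.columns:
            raise TraceError(
                f"column {col!r} not found in {path} (have {list(df.columns)})"
            )
    t = pd.to_numeric(df[time_column], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[signal_column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d non-finite rows while reading %s", n_dropped, path)
    t, y = t[keep], y[keep]
    if t.size < MIN_TRACE_LENGTH:
        raise TraceError(f"fewer than {MIN_TRACE_LENGTH} usable rows in {path}")
    return FluorescenceTrace(
        time_s=t, signal=y, wavelength_nm=wavelength_nm, rise_time_s=rise_time_s
    )


def write_trace_csv(trace: FluorescenceTrace, path, time_column: str = "time_s",
                    signal_column: str = "signal") -> None:
    """Write a trace back to CSV (inverse of :func:`read_trace_csv`)."""
    pd.DataFrame({time_column: trace.time_s, signal_column: trace.signal}).to_csv(
        path, index=False
    )


def detect_onset(
    trace: FluorescenceTrace,
    threshold_sd: float = 5.0,
    sustain: int = 5,
    min_baseline: int = 20,
) -> OnsetResult:
    """Locate the illumination onset from the dark baseline statistics.

    The onset is the first index at which the signal exceeds
    ``baseline_mean + threshold_sd * baseline_sd`` and stays above it for at
    least ``sustain`` samples, refined by walking back to the last sample at
    or below the baseline mean (so that detection is not biased late on
    slowly rising signals buried in noise).  ``F0_estimate`` is the median
    of the 10 samples following the onset.

    Raises ``TraceError("no rise detected")`` when no sustained crossing
    exists.  If the signal starts already risen (crossing within the first
    ``min_baseline`` samples) a ``no_baseline`` result anchored at index 0
    is returned with a logged warning.
    """
    y = trace.signal
    n = y.size

    def _crossing(mean: float, sd: float) -> int | None:
        thr = mean + threshold_sd * sd
        above = y > thr
        # sustained: `sustain` consecutive samples above threshold
        if sustain > 1:
            kernel = np.ones(sustain, dtype=int)
            runs = np.convolve(above.astype(int), kernel, mode="valid") == sustain
            idx = np.flatnonzero(runs)
        else:
            idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else None

    base = y[:min_baseline]
    cross = _crossing(float(base.mean()), float(base.std()))
    if cross is None:
        # either flat, or the rise started before the recording: tell the
        # two apart with a high-frequency noise estimate
        noise = float(np.std(np.diff(y)) / np.sqrt(2)) or 0.0
        risen = (
            float(np.ptp(y)) > 2 * threshold_sd * noise
            and y[-n // 10:].mean() - y[: n // 10].mean() > threshold_sd * noise
        )
        if not risen:
            raise TraceError("no rise detected")
        logger.warning("no baseline before rise; onset anchored at first sample")
        f0 = float(np.median(y[: min(10, n)]))
        return OnsetResult(0, float(trace.time_s[0]), f0, float(base.std()),
                           float(base.mean()), no_baseline=True)
    if cross >= min_baseline:
        # refine baseline statistics on everything before the first crossing
        base = y[:cross]
        refined = _crossing(float(base.mean()), float(base.std()))
        if refined is not None:
            cross = refined
    bmean, bsd = float(base.mean()), float(base.std())

    if cross < min_baseline:
        logger.warning("no baseline before rise; onset anchored at first sample")
        f0 = float(np.median(y[: min(10, n)]))
        return OnsetResult(0, float(trace.time_s[0]), f0, bsd, bmean, no_baseline=True)

    # walk back from the detection point to the last sample <= baseline mean
    onset = cross
    below = np.flatnonzero(y[:cross] <= bmean)
    if below.size:
        onset = int(below[-1]) + 1
    f0 = float(np.median(y[onset: onset + 10]))
    return OnsetResult(onset, float(trace.time_s[onset]), max(f0, 0.0), bsd, bmean)


def align_at_onset(trace: FluorescenceTrace, onset: OnsetResult) -> FluorescenceTrace:
    """Re-zero the time axis at the detected onset (baseline keeps t < 0)."""
    return trace.with_data(trace.time_s - onset.onset_time_s, trace.signal)


def moving_average(trace: FluorescenceTrace, window: int) -> FluorescenceTrace:
    """Centred boxcar smoothing; edges use shrunk windows (same length out)."""
    n = len(trace)
    if not (1 <= window <= n // 5):
        raise ValueError(f"window must be in [1, {n // 5}], got {window}")
    if window == 1:
        return trace.with_data(trace.time_s, trace.signal.copy())
    kernel = np.ones(window)
    num = np.convolve(trace.signal, kernel, mode="same")
    den = np.convolve(np.ones(n), kernel, mode="same")
    return trace.with_data(trace.time_s, num / den)


def log_subsample(trace: FluorescenceTrace, per_decade: int = 200) -> FluorescenceTrace:
    """Keep at most ``per_decade`` samples per decade of (positive) time.

    The trace must be onset-aligned.  Samples at t <= 0 (baseline) are kept
    as-is.  Positive-time samples are binned on a logarithmic grid anchored
    at the first positive timestamp, with bin width ``1/per_decade`` decade;
    the first sample of each occupied bin is retained, plus the final
    sample.  The rule is idempotent: subsampling twice equals once.
    """
    if per_decade < 10:
        raise ValueError(f"per_decade must be >= 10, got {per_decade}")
    t = trace.time_s
    pos = t > 0
    if not np.any(pos):
        return trace.with_data(t, trace.signal.copy())
    ipos = np.flatnonzero(pos)
    tp = t[ipos]
    bins = np.floor((np.log10(tp) - np.log10(tp[0])) * per_decade + 1e-12).astype(int)
    keep_local = np.r_[True, np.diff(bins) > 0]
    keep_local[-1] = True
    keep = np.zeros(t.size, dtype=bool)
    keep[~pos] = True
    keep[ipos[keep_local]] = True
    return trace.with_data(t[keep], trace.signal[keep])


def truncate_at_max(trace: FluorescenceTrace, smooth_window: int = 10) -> FluorescenceTrace:
    """Drop everything after the fluorescence maximum F_m.

    The rise can be followed by a decay (quenching); the stretched-
    exponential model only describes the rise, so the fit must stop at the
    maximum.  The argmax is located on a lightly smoothed copy (boxcar,
    ``smooth_window``) so isolated noise spikes do not truncate early.
    """
    w = min(smooth_window, max(1, len(trace) // 5))
    smoothed = moving_average(trace, w).signal if w > 1 else trace.signal
    imax = int(np.argmax(smoothed))
    if imax < MIN_TRACE_LENGTH - 1:
        return trace.with_data(trace.time_s, trace.signal.copy())
    return trace.with_data(trace.time_s[: imax + 1], trace.signal[: imax + 1])
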