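"""Synthetic ChlF rise curves from PSII two-electron-gate kinetics.

Two models generate ground truth for the fitting and calibration code:

* a **reduced** two-state model — photoactivation of Q_a at rate ``sigma*I``
  against a lumped back-reaction/transfer rate ``k`` — whose reduced-Q_a
  fraction has the closed form
  ``f(t) = sigma*I/(sigma*I + k) * (1 - exp(-(sigma*I + k) t))``,
  so the true characteristic time is ``tau = 1/(sigma*I + k)``;

* a **full** two-electron-gate model: six PSII states (Q_a and Q_b redox
  combinations {Qa Qb, Qa- Qb, Qa Qb-, Qa- Qb-, Qa Qb2-, Qa- Qb2-}) plus a
  shared plastoquinone pool.  Photoactivation (sigma*I) reduces Q_a from
  every oxidized-Q_a state; charge recombination (k_r) reopens Qa- Qb;
  electron transfer Qa- Qb <-> Qa Qb- (k1/k-1) and Qa- Qb- <-> Qa Qb2-
  (k2/k-2); exchange of doubly reduced Q_b with the pool,
  Qa Qb2- + PQ_ox <-> Qa Qb + PQ_red (k3/k-3) and
  Qa- Qb2- + PQ_ox <-> Qa- Qb + PQ_red (k4/k-4), with the exchange rates
  scaled by the relevant pool fraction.  Protonation of doubly reduced Q_b
  is neglected.

Fluorescence is mapped from the reduced-Q_a fraction:
``F(t) = F0_level + (Fm_level - F0_level) * f_Qa-(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import lfilter

from .trace import FluorescenceTrace

__all__ = [
    "KineticParams",
    "SimConfig",
    "SimulatedTrace",
    "simulate_reduced",
    "simulate_full",
    "reduced_qa_fraction",
    "generate_calibration_dataset",
    "add_artifacts",
    "synthetic_stretched_trace",
    "write_calibration_series",
]

#: full-model state labels, in state-vector order
STATE_LABELS = ("QaQb", "Qa-Qb", "QaQb-", "Qa-Qb-", "QaQb2-", "Qa-Qb2-")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-electron-gate scheme (all s^-1 except sigma).

    Defaults are literature orders of magnitude for PSII.  ``sigma`` is the
    photoactivation cross-section (m^2 mol^-1); multiplied by the photon
    flux I (E m^-2 s^-1) it gives the photoactivation rate constant.
    ``k_reduced`` is the lumped decay rate of the reduced two-state model,
    an *effective* constant at the measurement's time scale; it defaults to
    1e2 s^-1, the order of the intercept observed in 1/tau-vs-I
    calibrations (set it to None to fall back to ``k_r``).
    """

    sigma: float = 1.0e6
    k_r: float = 1.0e4
    k1: float = 5.0e3
    k_m1: float = 2.0e2
    k2: float = 1.5e3
    k_m2: float = 5.0e1
    k3: float = 1.0e2
    k_m3: float = 5.0e1
    k4: float = 1.0e2
    k_m4: float = 5.0e1
    pq_pool: float = 7.0
    k_reduced: float | None = 1.0e2
    recombination_all_states: bool = False

    @property
    def k_lumped(self) -> float:
        return self.k_r if self.k_reduced is None else self.k_reduced


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise settings of a simulated measurement."""

    intensity: float = 1.0e-3         # E m^-2 s^-1
    duration_s: float = 1.0
    pre_onset_s: float = 0.01
    rate_hz: float = 3.0e6
    n_points: int | None = None       # overrides rate_hz when set
    noise_sd_rel: float = 0.0         # Gaussian SD relative to (Fm - F0)
    led_rise_tau_s: float = 0.0       # 0 = ideal step
    F0_level: float = 1000.0
    Fm_level: float = 5000.0
    seed: int = 0

    def time_axis(self) -> np.ndarray:
        total = self.pre_onset_s + self.duration_s
        if self.n_points is not None:
            n = int(self.n_points)
        else:
            n = max(int(round(total * self.rate_hz)), 100)
        return np.linspace(-self.pre_onset_s, self.duration_s, n, endpoint=False)


@dataclass
class SimulatedTrace:
    """A synthetic trace together with its ground truth."""

    trace: FluorescenceTrace
    qa_reduced_fraction: np.ndarray
    true_tau: float                   # s; inf when I = 0
    params: KineticParams
    config: SimConfig
    states: np.ndarray | None = None  # (n_states, n_times) fractions
    pq_red: np.ndarray | None = None  # reduced-pool count per PSII


def reduced_qa_fraction(t, sigma_I: float, k: float) -> np.ndarray:
    """Closed-form reduced-Q_a fraction of the two-state model (t >= 0)."""
    t = np.asarray(t, dtype=float)
    rate = sigma_I + k
    if rate <= 0:
        return np.zeros_like(t)
    amp = sigma_I / rate
    return amp * -np.expm1(-rate * np.clip(t, 0.0, None))


def _fluorescence(fraction: np.ndarray, config: SimConfig) -> np.ndarray:
    return config.F0_level + (config.Fm_level - config.F0_level) * fraction


def add_artifacts(time_s: np.ndarray, signal: np.ndarray, config: SimConfig) -> np.ndarray:
    """Apply the LED turn-on convolution and additive Gaussian noise.

    The noiseless signal is convolved with an exponential source turn-on of
    time constant ``led_rise_tau_s`` (first-order low pass, implemented as
    an IIR filter on the uniform grid), then Gaussian noise of standard
    deviation ``noise_sd_rel * (Fm_level - F0_level)`` is added.
    Deterministic given ``config.seed``.
    """
    out = np.asarray(signal, dtype=float).copy()
    if config.led_rise_tau_s > 0:
        dt = float(np.median(np.diff(time_s)))
        alpha = -np.expm1(-dt / config.led_rise_tau_s)
        pos = time_s >= 0
        baseline = out[pos][0] if np.any(pos) else out[0]
        y = out[pos] - baseline
        out[pos] = baseline + lfilter([alpha], [1.0, alpha - 1.0], y)
    if config.noise_sd_rel > 0:
        rng = np.random.default_rng(config.seed)
        sd = config.noise_sd_rel * (config.Fm_level - config.F0_level)
        out = out + rng.normal(scale=sd, size=out.size)
    return out


def _package(time_s, fraction, params, config, states=None, pq_red=None,
             true_tau=float("inf")) -> SimulatedTrace:
    signal = add_artifacts(time_s, _fluorescence(fraction, config), config)
    trace = FluorescenceTrace(
        time_s=time_s, signal=signal, rate_hz=config.rate_hz,
        meta={"seed": config.seed, "intensity_E": config.intensity,
              "model_sigma": params.sigma},
    )
    return SimulatedTrace(trace=trace, qa_reduced_fraction=fraction,
                          true_tau=true_tau, params=params, config=config,
                          states=states, pq_red=pq_red)


def simulate_reduced(params: KineticParams, config: SimConfig) -> SimulatedTrace:
    """Simulate the two-state model (closed form, no ODE integration)."""
    if config.intensity < 0:
        raise ValueError("intensity must be nonnegative")
    t = config.time_axis()
    sigma_I = params.sigma * config.intensity
    k = params.k_lumped
    fraction = np.where(t >= 0, reduced_qa_fraction(t, sigma_I, k), 0.0)
    rate = sigma_I + k
    true_tau = 1.0 / rate if (rate > 0 and sigma_I > 0) else float("inf")
    return _package(t, fraction, params, config, true_tau=true_tau)


def _full_rhs(params: KineticParams, sigma_I: float):
    p = params
    pool = p.pq_pool

    def rhs(_t, x):
        x1, x2, x3, x4, x5, x6, pq_red = x
        f_ox = max(pool - pq_red, 0.0) / pool
        f_red = max(pq_red, 0.0) / pool
        photo1 = sigma_I * x1
        photo3 = sigma_I * x3
        photo5 = sigma_I * x5
        rec2 = p.k_r * x2
        rec4 = p.k_r * x4 if p.recombination_all_states else 0.0
        rec6 = p.k_r * x6 if p.recombination_all_states else 0.0
        t1f, t1b = p.k1 * x2, p.k_m1 * x3
        t2f, t2b = p.k2 * x4, p.k_m2 * x5
        ex3f, ex3b = p.k3 * f_ox * x5, p.k_m3 * f_red * x1
        ex4f, ex4b = p.k4 * f_ox * x6, p.k_m4 * f_red * x2
        dx1 = -photo1 + rec2 + ex3f - ex3b
        dx2 = photo1 - rec2 - t1f + t1b + ex4f - ex4b
        dx3 = t1f - t1b - photo3 + rec4
        dx4 = photo3 - rec4 - t2f + t2b
        dx5 = t2f - t2b - ex3f + ex3b - photo5 + rec6
        dx6 = photo5 - rec6 - ex4f + ex4b
        dpq = ex3f + ex4f - ex3b - ex4b
        return [dx1, dx2, dx3, dx4, dx5, dx6, dpq]

    return rhs


def simulate_full(params: KineticParams, config: SimConfig,
                  rtol: float = 1e-8, atol: float = 1e-10) -> SimulatedTrace:
    """Integrate the six-state two-electron-gate scheme with a PQ pool.

    Initial condition: all centres in Qa Qb (dark-adapted O level) and the
    plastoquinone pool fully oxidized.  Fluorescence reports the total
    reduced-Q_a fraction (states Qa- Qb, Qa- Qb-, Qa- Qb2-).
    """
    if config.intensity < 0:
        raise ValueError("intensity must be nonnegative")
    t = config.time_axis()
    tp = t[t >= 0]
    sigma_I = params.sigma * config.intensity
    x0 = np.array([1.0, 0, 0, 0, 0, 0, 0.0])
    sol = solve_ivp(
        _full_rhs(params, sigma_I), (0.0, float(max(tp[-1], 1e-12))), x0,
        t_eval=tp, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"full-model integration failed: {sol.message}; params={params}, "
            f"sigma_I={sigma_I}"
        )
    states = np.zeros((6, t.size))
    pq_red = np.zeros(t.size)
    states[0, t < 0] = 1.0
    states[:, t >= 0] = sol.y[:6]
    pq_red[t >= 0] = sol.y[6]
    fraction = states[1] + states[3] + states[5]
    # effective initial rate sets the expected tau of the light-limited step
    rate = sigma_I + (params.k_r + params.k1 if sigma_I > 0 else 0.0)
    true_tau = 1.0 / rate if sigma_I > 0 else float("inf")
    return _package(t, fraction, params, config, states=states, pq_red=pq_red,
                    true_tau=true_tau)


def synthetic_stretched_trace(
    tau_s: float,
    s: float = 1.24,
    F0_level: float = 1000.0,
    amplitude: float = 4000.0,
    duration_s: float | None = None,
    pre_onset_s: float | None = None,
    n_points: int = 200_000,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """Trace generated directly from the stretched-exponential rise law.

    Used as exact ground truth for the fit pipeline (the kinetic models
    only approximately follow the stretched-exponential form).  Duration
    defaults to 30 tau and the baseline to 2 tau (>= 1 ms).
    """
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    duration = duration_s if duration_s is not None else 30.0 * tau_s
    pre = pre_onset_s if pre_onset_s is not None else max(2.0 * tau_s, 1e-3)
    t = np.linspace(-pre, duration, int(n_points), endpoint=False)
    base = -np.expm1(-np.clip(t, 0.0, None) / tau_s)
    signal = F0_level + amplitude * np.power(base, s)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(scale=noise_sd_rel * amplitude, size=t.size)
    return FluorescenceTrace(time_s=t, signal=signal,
                             meta={"true_tau": tau_s, "true_s": s, "seed": seed})


def generate_calibration_dataset(
    params: KineticParams,
    intensities,
    config: SimConfig | None = None,
    model: str = "reduced",
    n_points_per_trace: int = 200_000,
) -> list[tuple[float, SimulatedTrace]]:
    """One seeded simulated trace per intensity (a calibration series).

    Each trace gets a duration adapted to its expected tau (25 tau of the
    reduced model, clipped to [2 ms, 1 s]) so that fast and slow traces are
    equally well resolved at a fixed point budget.  Seeds are offset by the
    series index, so duplicate intensities yield distinct noise.
    """
    intensities = list(intensities)
    if len(intensities) < 2:
        raise ValueError("need at least 2 intensities")
    config = config or SimConfig()
    sim = simulate_full if model == "full" else simulate_reduced
    out = []
    for i, intensity in enumerate(intensities):
        rate = params.sigma * intensity + params.k_lumped
        tau_guess = 1.0 / rate if rate > 0 else 1.0
        duration = float(np.clip(25.0 * tau_guess, 2e-3, 1.0))
        cfg = replace(
            config,
            intensity=float(intensity),
            duration_s=duration,
            pre_onset_s=max(0.05 * duration, 200e-6),
            n_points=n_points_per_trace,
            seed=config.seed + i,
        )
        out.append((float(intensity), sim(params, cfg)))
    return out


def write_calibration_series(dataset, directory, wavelength_nm: float = 470.0,
                             unit: str = "E") -> "pd.DataFrame":
    """Write traces + a series manifest CSV compatible with the CLI.

    The manifest lists (trace_path, intensity, unit, wavelength_nm) rows.
    Returns the manifest DataFrame; files land under ``directory``.
    """
    from pathlib import Path

    from .trace import write_trace_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (intensity, sim) in enumerate(dataset):
        path = directory / f"trace_{i:02d}.csv"
        write_trace_csv(sim.trace, path)
        rows.append({"trace_path": str(path), "intensity": intensity,
                     "unit": unit, "wavelength_nm": wavelength_nm})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "series.csv", index=False)
    return manifest
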