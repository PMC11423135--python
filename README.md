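# leafactin — leaf-based actinometry from the chlorophyll-fluorescence rise

Green leaves can serve as widely accessible actinometers.  When a
dark-adapted leaf is exposed to a jump of constant light, its chlorophyll
*a* fluorescence rises within a second from a minimum level F₀ (the O step
of the OJIP transient) to a maximum F_m (P).  The initial, light-limited
step of that rise reports on the photochemical reduction of the first
quinone acceptor Q_a of photosystem II, and its rate constant is
proportional to the incident photon flux:

```
1/τ = σ(λ) · I        ⇒        I = 1 / (σ(λ) · τ)
```

where τ is the characteristic time of the initial rise, I the photon flux
density (E m⁻² s⁻¹, 1 E = 1 mol photons) and σ(λ) the cross-section for
PSII photoactivation (m² mol⁻¹), which is remarkably stable across green
plant species (≈ 1.1 × 10⁶ m² mol⁻¹ at 470 nm, within roughly a factor
two).  Measuring τ from a fluorescence trace therefore measures absolute
light intensity — no spot-size calibration, no reference detector.

`leafactin` is the toolchain around that idea, aimed at anyone who needs
to calibrate a light source with a leaf and a photodetector:

* **trace handling** — CSV loading, illumination-onset detection,
  moving-average smoothing, logarithmic subsampling, truncation at F_m;
* **three-stage τ extraction** — a tri-stretched-exponential pre-fit of
  the whole rise, a constrained refit of
  `F(t) = F(0) + A·(1 − e^(−t/τ))^s` with s = 1.24 on [0, 3τ₁], and a
  final free refit on [0, 5τ], plus the (F_m − F₀)/F_m quality-control
  ratio (healthy leaves: 0.75–0.84);
* **cross-section calibration** — OLS of 1/τ against I over ≥ 7 intensity
  levels with two-pass z-score (|z| > 2) outlier rejection, and
  aggregation of σ across leaves;
* **wavelength transfer** — σ(λ) over the 400–650 nm action range from a
  normalized fluorescence excitation spectrum anchored at σ(470);
* **broadband sources** — scaling an unscaled emission spectrum S(λ) to
  absolute spectral photon flux via the action-spectrum integral
  AS = ∫ σ(λ) j(λ) dλ and S_I = 1/(τ·AS);
* **PSII simulator** — the two-electron-gate kinetic scheme (six
  Q_a/Q_b redox states plus a plastoquinone pool) and its reduced
  two-state limit, used as ground truth throughout the test suite;
* **unit conversion** — photon flux ↔ irradiance,
  I[W m⁻²] = h·c·N_A/λ · I[E m⁻² s⁻¹] ≈ 0.12 · I/λ[m].

The fitting and calibration steps are scikit-learn-style estimators
(`OJIPRiseFitter`, `CrossSectionCalibrator`) and compose with sklearn
tooling; thin functions (`fit_rise`, `fit_sigma`, …) wrap them.

## Worked example

Simulate a leaf exposed to 2 mE m⁻² s⁻¹ of blue light (reduced two-state
model, σ = 1.1 × 10⁶ m² mol⁻¹, lumped decay k = 100 s⁻¹, 1 % noise), then
retrieve the intensity from the trace alone:

```bash
leafactin simulate --model reduced --sigma 1.1e6 --intensity 2e-3 \
    --duration-s 0.02 --pre-onset-s 0.002 --n-points 200000 \
    --noise 0.01 --seed 1 --out example_trace.csv
leafactin intensity --trace example_trace.csv --wavelength-nm 470
```

The relevant part of the JSON report:

```json
{
  "tau_s": 0.0004355655325972021,
  "s": 0.9956223003744046,
  "qc_ratio": 0.7800460839801371,
  "intensity_E_m2_s": 0.002087150706508288,
  "intensity_W_m2": 531.2312148722691,
  "interval_E_m2_s": [0.001043575353254144, 0.004174301413016576]
}
```

The fitted τ = 435.6 µs is within 0.2 % of the simulator's true value
1/(σI + k) = 434.8 µs; the retrieved intensity, 2.09 mE m⁻² s⁻¹
(531 W m⁻² at 470 nm), brackets the true 2 mE m⁻² s⁻¹ well inside the
reported factor-two interval (the leaf-to-leaf spread of σ).  The QC
ratio 0.78 sits in the healthy range, so the point would be retained in a
calibration series.

The same workflow runs from Python:

```python
from leafactin import OJIPRiseFitter, read_trace_csv, retrieve_intensity

trace = read_trace_csv("example_trace.csv")
fitter = OJIPRiseFitter().fit(trace)
estimate = retrieve_intensity(fitter.tau_s_, wavelength_nm=470,
                              qc_ratio=fitter.qc_ratio_)
print(estimate.intensity, estimate.intensity_w)
```

Other subcommands: `leafactin convert` (E ↔ W), `leafactin fit` (τ only),
`leafactin calibrate` (σ from a series manifest), `leafactin spectrum`
(broadband source scaling).

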