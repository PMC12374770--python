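# layertof

Time-domain near-infrared spectroscopy (TD-NIRS) tooling for monitoring the
oxygenation of a deep tissue layer through a superficial one — the
transabdominal fetal-monitoring scenario: a maternal tissue layer of known
thickness over a semi-infinite fetal layer whose absorption coefficient
carries the physiological signal.

Continuous-wave NIRS integrates all detected photons, so the superficial
layer dominates the measurement. Time-domain NIRS records the full
distribution of times of flight (DTOF) of detected photons; late-arriving
photons have travelled deeper, which makes the DTOF separable into layer
contributions. `layertof` implements the complete pipeline from DTOFs to a
deep-layer tissue oxygenation index:

* **Forward models** — closed-form time-resolved reflectance of a
  semi-infinite medium, and the two-layer time-domain / steady-state
  diffusion solutions computed from the layered Green's function in
  (Hankel, frequency) space with an extrapolated boundary
  (`layertof.diffusion_forward`).
* **Monte Carlo validation** — MCML-style layered, time-resolved photon
  transport with per-layer partial-pathlength recording and Beer–Lambert
  perturbation re-weighting for fast pulsatile-signal synthesis
  (`layertof.mc_simulator`).
* **Preprocessing** — time-zero and amplitude calibration of raw TCSPC
  histograms against a reference medium, cropping, rebinning
  (`layertof.preprocessing`).
* **Inversion** — Levenberg–Marquardt estimation of both layers'
  (μa, μs′) from a single-distance transient, plus the multi-distance
  continuous-wave baseline fit (`layertof.inversion`).
* **Oximetry** — two-wavelength unmixing of absorption into relative
  HbO₂/Hb concentrations and the tissue oxygenation index
  TOI = 100·[HbO₂]/([HbO₂]+[Hb]) (`layertof.chromophores`).
* **Gating studies** — time-gated pulsatile signal retrieval, spectra,
  fetal signal-to-background ratios, and the CW-vs-TD accuracy comparison
  (`layertof.gating_analysis`, `layertof.experiments`).

## Model sketch

Within each layer light transport follows the diffusion approximation with
diffusion coefficient `D = 1/(3 μs′)` and energy speed `v = c/n`. In
spatial-frequency (Hankel) and temporal-frequency space, the two-layer
fluence at the surface from an isotropic source at depth `z0 = 1/μs′₁` with
an extrapolated zero-fluence boundary at `z = −zb`, `zb = 2AD₁`, is

```
φ(s, ω) = e^(−a₁z0) (1 − e^(−2a₁zb)) ·
          [D₁a₁(1+e₁) + D₂a₂(1−e₁)] / (2D₁a₁ [D₁a₁(1+E) + D₂a₂(1−E)])
aᵢ² = s² + (μaᵢ + iω/vᵢ)/Dᵢ,  e₁ = e^(−2a₁(L−z0)),  E = e^(−2a₁(L+zb))
```

with `L` the top-layer thickness and `A` the Fresnel boundary mismatch
factor. Reflectance is `R = φ/(2A)`, inverse-Hankel-transformed by
Gauss–Legendre quadrature and FFT'd to the time domain. Measured transients
are fitted by Levenberg–Marquardt in log-parameter space with Poisson
weighting; absorption at 740 and 850 nm (straddling the ~800 nm hemoglobin
isosbestic point) is unmixed into HbO₂ and Hb via the modified
Beer–Lambert relation `μa = ln10 (ε_HbO₂ c_HbO₂ + ε_Hb c_Hb)`.

## Worked example

```python
import numpy as np
from layertof import (OpticalLayer, TwoLayerMedium, DetectionGeometry, TimeGrid,
                      two_layer_td_reflectance, sample_counts, fit_two_layer_td,
                      load_default_extinction_table, unmix_two_wavelengths)

medium = TwoLayerMedium(
    top=OpticalLayer(mua=0.11, musp=11.19, n=1.4, thickness=0.96),  # maternal
    bottom=OpticalLayer(mua=0.09333, musp=9.551, n=1.4),            # fetal
)
geom = DetectionGeometry(rho=2.0, wavelength=850.0)
grid = TimeGrid(0.0, 5.0, 200)

density = two_layer_td_reflectance(medium, geom, grid)   # noise-free DTOF
counts = sample_counts(density, 1e6, seed=3)             # TCSPC shot noise
fit = fit_two_layer_td(counts, geom, top_thickness=0.96)
print({k: round(v, 5) for k, v in fit.estimates.items() if k != "amplitude"})
err = abs(fit["mua2"] - 0.09333) / 0.09333 * 100
print(f"deep-layer mua relative error: {err:.2f}%")
```

prints (seed 3)

```
{'mua1': 0.118, 'musp1': 11.32682, 'mua2': 0.09181, 'musp2': 15.32757}
deep-layer mua relative error: 1.63%
```

i.e. the fit recovers the fetal absorption coefficient (truth 0.09333 cm⁻¹)
from a million-count noisy transient to within a couple of percent — the
quantity the oximetry needs — while the deep-layer scattering coefficient
is, as expected, only weakly identified from a single distance. Fitting
both wavelengths and calling `unmix_two_wavelengths` converts the two
fetal absorptions into the TOI.

A CLI mirrors the main steps (`layertof forward|mc|calibrate|fit|study
|gate-study`), e.g.:

```bash
layertof forward --config medium.yaml --rho 2.0 --tmax 5 --bins 400 --out dtof.csv
layertof fit --transient dtof.csv --thickness-cm 0.96 --out fit.json
layertof study cw-vs-td --seeds 20 --out report/
```

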