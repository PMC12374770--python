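# Methods

## Scope and model

`layertof` targets deep-layer tissue oximetry through a superficial layer
with time-domain NIRS. The medium is a plane-parallel two-layer slab: a
finite top ("maternal") layer of known thickness over a semi-infinite
bottom ("fetal") layer, each homogeneous with absorption μa (cm⁻¹),
reduced scattering μs′ (cm⁻¹) and refractive index n. The measurement is
the distribution of times of flight (DTOF) of photons re-emitted at the
surface at distance ρ from a pencil-beam source. Units are cm, cm⁻¹, ns,
nm; c = 29.9792458 cm/ns.

Assumptions: the diffusion approximation holds in both layers (μs′ ≫ μa —
a warning is emitted when violated); layer properties are constant over a
frame's integration time; the top thickness is known (clinically from
ultrasound, in phantoms by construction) and never fitted.

## Forward solutions

**Semi-infinite closed form.** Isotropic point source at depth z₀ = 1/μs′
plus a negative image across the extrapolated boundary z = −z_b,
z_b = 2AD; surface fluence → reflectance via R = Φ/(2A). Used as the
inversion's initialization model and as an oracle for the layered code.

**Two-layer solution.** Solved in Hankel space (s) × temporal frequency
(ω): with aᵢ² = s² + (μaᵢ + iω/vᵢ)/Dᵢ, continuity of fluence and flux at
the interface and Φ = 0 at z = −z_b give the surface Green's function
written entirely in decaying exponentials (overflow-safe at large s; see
the docstrings in `diffusion_forward`). For equal layers it reduces
algebraically to the image-source semi-infinite kernel — the basis of the
homogeneous-limit test, which holds to ~2×10⁻⁴ against the closed form.

Conventions, each of which is a choice rather than a physical necessity:

* D = 1/(3μs′), absorption-independent (switchable to 1/(3(μa+μs′)) via
  `d_convention`), matching the layered-solution literature.
* Boundary factor A from the Fresnel-integral effective reflection
  coefficient (R_φ, R_j moments); A(n_rel=1) = 1 exactly, A(1.4) ≈ 2.95.
* Reflectance is fluence-based, R = Φ(ρ, z=0, t)/(2A). A Fick-flux
  variant exists in the literature; with free fit amplitudes the choice
  mostly rescales the transient.
* Refractive indices are not part of the study conditions anywhere
  upstream; tissue default n = 1.4 for both layers, ambient n = 1.0.
* Source depth z₀ = 1/μs′₁ is clamped to 0.99·L for extremely thin or
  weakly scattering top layers so the one-source representation stays in
  layer 1.

**Numerics.** The inverse Hankel transform uses fixed-order
Gauss–Legendre quadrature on s ∈ [0, s_max] with s_max = 22·μs′₁-decay
lengths of the kernel tail (truncation ~3×10⁻¹⁰) and order chosen from
the J₀(sρ) cycle count (≥512); an order-doubling check (rtol 10⁻⁶, one
further doubling before declaring failure) guards the first evaluation of
each evaluator. Time-domain synthesis evaluates the spectrum on an rfft
grid with internal step ≤ 25 ps and a zero-padding factor 4 (pad 2 inside
the fit loop), phase-shifts to land samples exactly on requested bin
centers (bin-center convention), and clips negative inverse-transform
ringing at zero, warning if the clipped mass exceeds 10⁻³ of the total.

## Monte Carlo

MCML-style layered transport with implicit-capture weighting (per
interaction w ← w·μs/μt), Henyey–Greenstein phase function, Fresnel
reflection/refraction at all index steps, Russian roulette (threshold
10⁻⁴, survival 0.1). The paper-level studies specify only μs′, so g = 0.9
and μs = μs′/(1−g). The detector is an annulus ρ ± 0.05 cm accepting all
exit angles (an NA cut is available). Arrival time is the optical
pathlength ΣnᵢLᵢ/c, consistent with v = c/n in the diffusion model.
Photons are killed once their optical path exceeds the time window —
an exact truncation for DTOF estimation on that window.

Per-photon randomness derives from (seed, photon index) via SplitMix64
feeding an xorshift64* stream: results are bit-reproducible for a given
seed and independent of batching. Detected weight, squared weight (for
per-bin standard errors), hit counts and per-layer pathlength sums are
recorded per arrival bin.

**Perturbation re-weighting.** For small per-layer absorption changes
Δμaᵢ, the detected DTOF is re-weighted per bin by exp(−ΣᵢΔμaᵢ·L̄ᵢ(t))
using the mean detected per-layer pathlengths. This is first-order exact
(it replaces the per-photon average of exp(−ΔμaΣL) by the exponential of
the average); a warning is emitted above 20% relative perturbation. The
pulsatile-stream generator is built on it so that a single baseline MC
run yields arbitrarily long modulated frame streams.

## Calibration and preprocessing

A calibration measurement on a reference medium of known properties
determines, per wavelength, the laser emission time t₀ and an amplitude
factor such that measured(t) ≈ amplitude·model(t−t₀): integer-channel
grid search with closed-form amplitude at each shift and parabolic
sub-channel refinement of the weighted-least-squares loss. Background is
a constant estimated from pre-peak channels, subtracted and floored at 0.
The instrument response is treated as a delta after the t₀ shift — the
pipeline normalizes against theory rather than deconvolving; an IRF
convolution hook is a natural extension point. Rebinning is
mass-conserving (cumulative-sum interpolation).

## Inversion

All fits are Levenberg–Marquardt (`scipy.optimize.least_squares`,
method="lm") on log-transformed coefficients, which enforces positivity
without active bounds; the bound box (μa ∈ [10⁻³, 1], μs′ ∈ [1, 30] cm⁻¹)
is checked post hoc and flags the result if violated. Default loss:
weighted least squares with per-bin Poisson variance (1/max(counts, 1));
Poisson deviance and log-domain losses are available. The two-layer TD
fit frees {μa₁, μs′₁, μa₂, μs′₂, amplitude}; initialization fits a
semi-infinite model first and seeds both layers with its result. The two
wavelengths are fitted independently and combined only at the unmixing
stage.

**Fit window.** From the bin where the rising edge first reaches 50% of
the peak to the last bin above 0.1% of the peak. The early cut avoids
IRF-dominated bins in real data. The deep tail is retained because
late-arriving photons carry most of the deep-layer information — the
package's own depth-sensitivity analysis shows the fetal-layer partial
pathlength grows monotonically with arrival time — and Poisson weighting
already down-weights low-count bins correctly. At the study conditions
(10⁶ counts) a 1%-of-peak tail cut roughly quadruples the median
deep-layer absorption error; 0.1% is the package default.

**CW baseline.** The steady-state layered model fitted to log intensities
at 1–4 cm. The amplitude is treated as a known calibration constant by
default (simulated data carry an absolute scale); profiling it instead
costs one degree of freedom and is rejected when it would leave the four
layer coefficients underdetermined by four distances. The CW fit's
near-interpolating character at four distances is precisely why its
deep-layer error is larger than the TD fit's — the ordering the studies
quantify.

## Oximetry

Modified Beer–Lambert mixing with a decadic extinction table and explicit
ln 10. The bundled table (`data/hb_extinction_synthetic.tsv`) is a
synthetic compilation: realistic magnitudes and spectral shape for
HbO₂/Hb over 600–1000 nm with the isosbestic crossing at ~797 nm and
well-separated coefficients at 740/850 nm. All shipped analyses use
relative concentrations and TOI, which depend only on the table's
internal consistency, not its absolute accuracy; for absolute
concentrations substitute a metrological table via `ExtinctionTable`.
Water/lipid background absorption is ignored by default (optional fixed
offsets per wavelength). Negative unmixed concentrations are flagged and
excluded from TOI (reported NaN) rather than clipped, which would bias
TOI silently; solver-level rounding residue (|c| ≲ 10⁻⁹ of scale) is
snapped to zero.

## Study conditions (synthetic-data generator)

The generator reproduces the validation scenario: maternal layer
μa = 0.11 cm⁻¹, μs′ = 11.19 cm⁻¹, 9.6 mm thick; fetal layer μs′ = 9.551
cm⁻¹ with μa ∈ {0.08488, 0.08910, 0.09333, 0.09755, 0.1018} cm⁻¹ for
TOI ∈ {20…60}%; TD detector at ρ = 2 cm, CW detectors at 1–4 cm; Poisson
shot noise at 10⁶ detected counts per transient (CW budgets matched at
the shared 2 cm detector). The pulsatile study modulates maternal/fetal
absorption sinusoidally at 1.3/2.1 Hz with 2% modulation depth, 20 Hz
frame rate, 60 s duration, 10⁵ counts per frame; the late gate opens at
the 70% cumulative-count time. The occlusion demo drives a
piecewise-linear TOI trajectory (plateau → ramp-down during occlusion →
post-release overshoot → recovery) at 50 μM total hemoglobin through the
full pipeline.

What the generator does **not** emulate: instrument response functions
and afterpulsing, dark counts beyond a constant offset, motion and
respiration artifacts, layer-thickness uncertainty, curvature of real
anatomy, and >2 chromophores. Passing tests therefore demonstrate the
correctness and statistical behaviour of the algorithms under the stated
two-layer diffusion/MC physics, not clinical performance.

## Problem sizes

The test suite runs the Monte Carlo–diffusion equivalence at 10⁷ launched
photons on a 3 ns window (the populated-bin region at ρ = 2 cm) with a
3×10⁶-photon independent run as the perturbation oracle; the pulsatile
studies reuse one 4×10⁵-photon baseline. Recovery and CW-vs-TD studies
use 10⁶-count transients over 5 and 20 seeds respectively. These sizes
make each claim's statistics decisive (the MC comparisons have ≥10³
weight in every asserted bin) while keeping the full suite desk-scale.

## Known limitations

* Two layers only; N > 2, curved geometries, anisotropic diffusion and
  interior fluence maps are out of scope.
* The perturbation re-weighting is biased at large Δμa (Jensen gap on
  exp); it is used at ≤2% modulation where the bias is ≪ shot noise.
* The covariance reported by the fits is a Gauss–Newton proxy for
  identifiability comparisons, not a calibrated confidence region.
* TOI from two wavelengths is exactly determined; gross fit failures
  propagate to NaN rather than being detectable by residual diagnostics.
* The CW baseline presumes calibrated absolute intensities; relative-only
  CW data would need ≥5 distances or extra constraints.
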