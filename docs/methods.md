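# Methods

## The measurement being modelled

A pendant drop of surfactant solution hangs from a capillary inside a
thermostated chamber. After the surface tension equilibrates, the
instrument imposes small sinusoidal oscillations of the drop volume (below
10% relative) at frequencies between 0.01 and 0.2 Hz and records the drop
surface area `A(t)` (mm², from Young–Laplace profile fitting, which is
outside this package's scope) and the surface tension `σ(t)` (mN/m,
precision ~0.1 mN/m), nominally once per second. The complex surface
dilational modulus at the oscillation frequency ν is

```
ε = ε_r + i ε_i = A₀ · Δσ₁ / ΔA₁
```

with `A₀` the mean drop area and `Δσ₁`, `ΔA₁` the complex fundamental
harmonic components of tension and area. `ε_r` is the storage (elastic)
part, `ε_i` the loss (viscous) part.

**Phase/sign convention.** Harmonics are written `a·sin(2πkνt + φ)`, and a
harmonic's complex coefficient is `a·e^{iφ}`. The synthetic generator
produces `σ(t) = σ_base + |ε|·a·sin(2πνt + φ)` with `φ = atan2(ε_i, ε_r)`,
i.e. positive `ε_i` corresponds to the tension harmonic *leading* the area
harmonic — the standard `e^{+iωt}` convention under which the
Lucassen–van den Tempel model has both parts non-negative. Analyzer and
generator share this convention, so every linear noiseless trace
round-trips to its generating modulus (verified to ~1e-13).

## Harmonic estimation

Amplitudes and phases at `kν` (k = 1..4 by default; the distortion
statistic uses only k = 1, 2) come from least-squares regression of the
signal onto `{1, t, cos(2πkνt), sin(2πkνt)}` rather than FFT binning: the
regression is unbiased for traces that need not span an integer number of
periods, tolerates irregular sampling, and the joint linear term removes
slow equilibration drift. Preconditions: at least 3 fundamental periods
and all fitted harmonics below the Nyquist frequency.

**Frequency refinement.** Instrument frequency jitter is absorbed by
refining ν within ±5% of the nominal value before decomposition. The
refinement minimises the regression residual (maximises explained energy).
Maximising the fitted fundamental *amplitude* — the obvious alternative —
is biased here: with the drift column in the basis, a slightly detuned
sinusoid can trade against the linear term and inflate the apparent
amplitude (measured bias ~1e-3 relative in frequency). The residual
criterion has its exact optimum at the true frequency. The refined
frequency is estimated once, from the clean imposed area signal, and used
for both signals so their phase difference stays consistent.

## Loess smoothing and its exact inversion

Raw tension traces are smoothed with a locally weighted quadratic
regression (tricube weights; window 0.3 of one oscillation period,
expressed internally as a fraction of points; one-sided windows at the
ends). On uniform grids the interior reduces to a fixed equivalent-kernel
convolution. The smoother is implemented in-package because the analysis
needs local *quadratic* fits evaluated on the trace's own grid.

Any real smoother attenuates the very harmonics being measured (about
0.2% at the fundamental for the default window — far above the 1e-9
round-trip accuracy the analysis targets). Because Loess is linear, its
action on the harmonic basis can be measured exactly on the actual time
grid: each basis function is passed through the smoother and regressed
back onto the basis, giving a response matrix `M` (including edge effects
and harmonic-to-harmonic cross-talk; constant and linear columns pass
through unchanged for degree ≥ 1). Solving `M x = coeffs(smoothed signal)`
recovers the unsmoothed harmonic coefficients exactly for any in-basis
content while out-of-basis noise is still suppressed. The smoothing can be
disabled (`SmoothingConfig(enabled=False)`); smoothed and raw analyses of
a noiseless linear trace then agree to ~1e-13.

**Quality flags.** If the relative area amplitude `|ΔA₁|/A₀` is below 1e-4
the trace carries no excitation and the analysis refuses it; above 0.2 it
is outside the linear-response regime. If the fundamental tension
amplitude is below 3× its own standard error (residual sd × √(2/N)) the
point is flagged `no_response` with `ε = 0` and an undefined (NaN)
harmonic ratio. The 3× standard-error form is used instead of 3× the raw
residual sd because the amplitude estimator averages N samples; the raw-sd
floor would discard many-sigma detections.

## Lucassen–van den Tempel model and fit

For diffusion-controlled exchange between a soluble monolayer and the bulk,

```
ε(ν) = ε₀ (1 + ξ + iξ) / (1 + 2ξ + 2ξ²),   ξ = √(ν_D / 2ν)
```

`ε₀` (mN/m) is the Gibbs elasticity (insoluble-monolayer limit), `ν_D`
(Hz) the characteristic diffusion frequency. Within the model
`0 < ε_i < ε_r < ε₀` for all ξ > 0 and the phase angle stays below 45°, so
a measured loss part exceeding the storage part is a model-violation
diagnostic (micellar relaxation, mixed layers, shear effects) rather than
a fitting failure.

`LvdTModel` fits (ε₀, ν_D) by bounded least squares (`ε₀ ∈ (0, 500]` mN/m,
`ν_D ∈ [0, 10]` Hz) from a 3×3 multi-start grid (ε₀ ∈ {5, 20, 80},
ν_D ∈ {1e-4, 1e-2, 1}), keeping the best converged optimum. The default
target is the real part only, because the loss part is the first to leave
the diffusional regime; a joint complex fit is available as an extension.
The objective is unweighted (optional per-point weights accepted);
1-sigma uncertainties come from the linearised covariance at the optimum.
On noiseless self-generated spectra the fit recovers generating parameters
to better than 0.1% (in practice exactly); synthetic frequency sweeps
default to 15 log-spaced points in [0.005, 0.2] Hz, bracketing the
instrument band, and noiseless recovery is insensitive to the grid.

## Mixed-surfactant adsorption isotherm

The equilibrium model treats the interface as a quasi-two-dimensional
electrolyte. For components i with charge `z_i`, surface activity `b_i`
(m³/mol), molar area `ω_i` (m²/mol) and Frumkin interaction matrix `a_ij`
(a > 0 = attraction):

1. subsurface concentrations: `c_iˢ = c_i · exp(−z_i F ψ_s / RT)`;
2. mixed Frumkin isotherm:
   `b_i c_iˢ = θ_i/(1 − Σθ_j) · exp(−2 Σ_j a_ij θ_j)`;
3. surface equation of state:
   `Π = −(RT/ω_ref)[ln(1 − Σθ) + Σ a_ij θ_i θ_j] + Π_el` with `ω_ref` the
   major component's molar area;
4. Gouy–Chapman closure:
   `F Σ z_i θ_i / ω_ref = √(8 ε_w ε₀ᵛ RT I) · sinh(F ψ_s / 2RT)` and
   `Π_el = (8 RT I / κ)[cosh(F ψ_s / 2RT) − 1]`, κ the inverse Debye
   length, I the ionic strength from all ions (surfactant ions, their
   counterions enforcing bulk electroneutrality, 1:1 salt).

σ(c) = σ₀ − Π, clamped at its CMC value above a configured CMC (micellar
equilibria are not modelled). Switching off charges, interactions and the
second component reduces the model *exactly* to the Langmuir isotherm and
Szyszkowski equation, and the isotherm/equation-of-state pair is
Gibbs-consistent (`Γ = θ/ω = −dσ/d(RT ln c)` analytically; property-tested
numerically at 1%). Temperature defaults to 295 K (22 °C), σ₀ to
72.5 mN/m, water relative permittivity to 78.5.

**Solver.** Coverages at given ψ_s come from a fixed-point iteration with
exact Langmuir start (full steps, damped retry, Newton fallback; residual
< 1e-10 enforced); ψ_s from a bracketed Brent root of the charge balance
with geometric bracket expansion. Fully deterministic.

**Mixture composition.** The minority (dimer-forming) species is assumed
fully dimerised: dimer concentration `f·c`, monomer `(1−f)·c`. The molar
fraction f is fixed from composition knowledge (0.2% dodecanoate for
fresh solutions, 18% LAS after prolonged storage), not fitted, by default;
it can be freed explicitly. Fitting (`MixedIsothermModel`) optimises any
subset of {b_i, ω_i, a_ij, f} by bounded least squares, b and ω in log10
space with multiplicative multi-start, residuals in mN/m at the measured
concentrations. A covariance condition number above 1e10 triggers an
under-determination warning.

**CMC detection.** Two straight lines fitted to σ vs log₁₀(c) over every
admissible split (≥ 4 points per side); the split minimising the total
squared residual wins, and the CMC is the intersection. Exactly piecewise
data are recovered exactly; single-slope data raise a no-breakpoint error.

## Synthetic data generator

The generator emulates the instrument under the study conditions: area
`A(t) = A₀(1 + a·sin 2πνt)` with `A₀ = 25 mm²` (≈ 11 µL drop) and default
relative amplitude a = 0.1 (the instrument actually controls volume; the
spherical-drop conversion `dA/A = (2/3)·dV/V` is provided, and the
condition suites use a = 0.067, i.e. 10% volume); tension as in the phase
convention above plus optional distortion and Gaussian noise of sd
0.1 mN/m (the stated measurement precision); sample rate 1 Hz as recorded,
with oversampling available because 0.2 Hz at 1 Hz sampling is only 5
samples per period; 10 periods per trace by default.

**Nonlinearity.** Near and above the CMC the measured tension waveform is
distorted at compression (desorbing surfactant is absorbed into micelles,
so desorption is not attenuated), which pumps energy into even harmonics.
The generator models this as a quadratic term `β·(a sin 2πνt)²` rather
than a mechanistic micelle-exchange model: the sin² surrogate has exactly
known second-harmonic content (`β a²/2`), which makes the distortion
statistic testable analytically (`β = 2·r·|ε|/a` yields harmonic ratio r).
It does not claim to match the true waveform shape.

**Reference conditions.** The condition suite writes one trace per
(concentration, frequency) pair over 0.2–1.5 mM at 0.01 and 0.1 Hz, using
the tabulated reference LvdT parameters below the CMC — (ε₀ mN/m, ν_D Hz)
= (30.1, 0.0032) at 0.2 mM, (73.9, 0.02) at 0.3, (45.3, 0.0081) at 0.5,
(26.9, 0.03) at 0.8, (12.6, 0.06) at 1.0 — and a flagged extrapolation
(10.0, 0.10) for 1.5 mM, where no reference fit exists and the diffusional
model no longer strictly applies; the extrapolation continues the
decreasing-ε₀ / increasing-ν_D trend while keeping the signal above the
instrument noise. The distortion ramps with concentration (target ratios
0, 0.05, 0.15, 0.30, 0.30), matching the observed ~0.5 mM onset of the
nonlinear response that grows to the CMC (1 mM) and levels off. A
frequency-sweep variant (7 log-spaced frequencies per concentration,
oversampled to 20 points per period) feeds the end-to-end pipeline, whose
LvdT stage needs ≥ 3 frequencies.

The default LAE-like mixture (`lae_reference_system`) uses b = 30 m³/mol,
ω = 2.5e5 m²/mol, z = +1 for the monomer and b = 2e4 m³/mol, ω = 4e5
m²/mol for the heterodimer (neutral LAE–dodecanoate at f = 0.002 fresh;
+1 LAE–LAS at f = 0.18 aged), a = 1.0, CMC 1.05 mM. These values were
chosen once so the model curve shows the study's qualitative fingerprints
— surface-activity onset near 1e-4 mol/dm³, σ at the CMC near 25 mN/m,
salt screening lowering σ — and are illustrative defaults, not fitted
constants; the aged variant is qualitative only.

**What the generator does not emulate**: drop-shape artefacts and
Young–Laplace fitting errors, slow monotonic equilibration drifts beyond
the linear term, temperature fluctuations, correlated (non-white) noise,
the true asymmetric above-CMC waveform, and micellar kinetics in the
isotherm. Passing round-trip tests therefore demonstrates the estimators'
correctness under the stated noise model, not robustness to every
instrumental pathology.

## Problem sizes and tolerances

Synthetic traces use 10 periods at ≥ 10 samples per period; LvdT recovery
runs on 15-point noiseless spectra; Monte-Carlo checks use 100–200
replicates (trace round trips, CMC noise, LvdT noise); isotherm grids use
20–50 log-spaced concentrations. Key numerical tolerances: harmonic
regression vs quadrature oracle 1e-6; noiseless modulus round trip 1e-9;
coverage-solver residual 1e-10; Szyszkowski limit 1e-8 relative; fit
recoveries 0.1% (LvdT, noiseless) and 1% (isotherm, noiseless). Degenerate
inputs (zero concentration, zero elasticity, constant spectra, flat
tension) are handled explicitly and tested.

## Known limitations

- The exact published appendix form of the mixture model this
  reconstruction follows was not available; the implementation is the
  standard realisation of the quasi-two-dimensional electrolyte family,
  so point-by-point agreement with any particular published fitted curve
  is not guaranteed.
- Per-component molar areas enter the equation of state only through the
  single reference area; the area-ratio refinement is not implemented.
- The above-CMC branch is a clamp, not a micellar equilibrium model.
- The LvdT fit assumes independent, equally weighted modulus points;
  uncertainties are linearised and do not account for the trace-analysis
  error correlation between ε_r and ε_i.
- Hydrolysis is represented only through the fixed composition fraction
  f; there is no rate law or storage-time model.
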