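# oscdrop

Surface dilational rheology and adsorption-isotherm analysis for
multicomponent surfactant systems, built around the oscillating pendant-drop
experiment.

Aqueous solutions of ethyl lauroyl arginate (LAE) — an amino-acid-based
cationic food-preservative surfactant — are never a single-component system:
synthesis residues and slow hydrolysis supply lauric acid / dodecanoate and
N&alpha;-lauroyl-arginine (LAS), which pair with LAE into highly
surface-active heterodimers. `oscdrop` implements the computational side of
characterising such a system:

- **Trace analysis** — turn an oscillating-drop time series (drop area
  `A(t)`, surface tension `σ(t)`) into the complex surface dilational
  modulus `ε = ε_r + iε_i = A₀·Δσ₁/ΔA₁`, where `Δσ₁`, `ΔA₁` are the
  fundamental harmonic components of the (Loess-smoothed) tension and the
  imposed area, plus the second-to-first tension harmonic ratio
  `|F(Δσ)₂|/|F(Δσ)₁|` that quantifies the nonlinear (micellar) response.
- **Diffusional viscoelasticity** — evaluate and fit the
  Lucassen–van den Tempel (LvdT) model
  `ε(ν) = ε₀·(1 + ξ + iξ)/(1 + 2ξ + 2ξ²)`, `ξ = √(ν_D/2ν)`, with Gibbs
  elasticity `ε₀` and diffusion frequency `ν_D`.
- **Mixed adsorption isotherm** — a quasi-two-dimensional electrolyte model
  (mixed Frumkin isotherm at Boltzmann-corrected subsurface concentrations,
  Gouy–Chapman diffuse-layer closure) producing and fitting `σ(c)` curves
  for monomer + heterodimer + salt mixtures, with two-segment breakpoint
  detection of the critical micelle concentration (CMC).
- **Synthetic tensiometer** — a generator for drop-oscillation traces
  (linear and harmonically distorted) and isotherm datasets with realistic
  instrument noise, so the whole pipeline is testable without access to a
  tensiometer.

The fitting components are scikit-learn style estimators (`LvdTModel`,
`MixedIsothermModel`, `CMCBreakpoint`) with `fit`/`predict` and
underscore-suffixed fitted attributes; module-level functions (`fit_lvdt`,
`fit_isotherm`, `detect_cmc`, `dilational_modulus`, ...) wrap them.

## Worked example

```python
import numpy as np
from oscdrop import (TraceRecipe, generate_oscillation_trace, dilational_modulus,
                     LvdTModel, LvdTParams, lvdt_modulus)

# synthesise one noisy oscillating-drop trace (0.1 Hz, LvdT response)
recipe = TraceRecipe(frequency=0.1, lvdt=LvdTParams(26.9, 0.03),
                     amplitude_fraction=0.067, noise_sd=0.1, seed=42,
                     sample_rate=2.0)
trace = generate_oscillation_trace(recipe)
point = dilational_modulus(trace)
print(f"eps_r = {point.eps_real:.2f} mN/m, eps_i = {point.eps_imag:.2f} mN/m, "
      f"ratio = {point.harmonic_ratio:.4f}, flag = {point.quality_flag}")

# fit the LvdT model to a real-part modulus spectrum
freqs = np.logspace(np.log10(0.005), np.log10(0.2), 15)
y = lvdt_modulus(LvdTParams(30.1, 0.0032), freqs).real
model = LvdTModel(part="real").fit(freqs, y)
print(f"eps0 = {model.eps0_:.4f} mN/m, nu_D = {model.nu_d_:.6f} Hz")
```

prints

```
eps_r = 18.12 mN/m, eps_i = 5.17 mN/m, ratio = 0.0123, flag = ok
eps0 = 30.1000 mN/m, nu_D = 0.003200 Hz
```

The analysed modulus matches the generating model value at 0.1 Hz
(17.99 + 5.02i mN/m) within the noise-propagated uncertainty, the harmonic
ratio is at the noise level (no distortion was injected), and the
noiseless spectrum fit recovers the generating parameters exactly.

A command-line interface mirrors the library:

```bash
oscdrop simulate --out-dir traces --seed 1       # synthetic condition grid
oscdrop analyze-trace traces/*.csv --out modulus.csv
oscdrop fit-lvdt modulus.csv --out lvdt_fits.csv
oscdrop fit-isotherm iso.csv --config system.yaml --out fit.csv
oscdrop detect-cmc iso.csv
oscdrop report --out-dir run --seed 1            # end-to-end with manifest
```

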