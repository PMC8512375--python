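"""Synthetic tensiometer data: oscillating-drop traces and isotherms.

The generator emulates a pendant-drop instrument driving small sinusoidal
area oscillations (sampling once per second, oscillation frequencies
0.01-0.2 Hz, relative amplitude below 10%) and recording the surface
tension response with 0.1 mN/m measurement precision. A linear
viscoelastic response is parameterised by a complex dilational modulus
(given explicitly or evaluated from the LvdT model); an optional quadratic
(sin^2) distortion injects the even-harmonic content that micellar
desorption produces near the CMC, with analytically known second-harmonic
amplitude so the distortion statistic can be tested exactly.

Every generated trace is the analyzer's adjoint: a noiseless linear trace
round-trips through :func:`oscdrop.modulus.dilational_modulus` to its
generating modulus at machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .isotherm import IsothermDataset, MixtureSystem, SurfactantComponent, surface_tension_curve
from .lvdt import LvdTParams, lvdt_modulus
from .trace import OscillationTrace

#: reference LvdT best-fit parameters (eps0 mN/m, nu_D Hz) for aqueous LAE
#: at 22 C, by bulk concentration in mM; derived from oscillating-drop
#: measurements below the CMC.
LVDT_REFERENCE_FITS: dict[float, LvdTParams] = {
    0.2: LvdTParams(30.1, 0.0032),
    0.3: LvdTParams(73.9, 0.02),
    0.5: LvdTParams(45.3, 0.0081),
    0.8: LvdTParams(26.9, 0.03),
    1.0: LvdTParams(12.6, 0.06),
}

#: extrapolated parameters for the above-CMC 1.5 mM condition (no reference
#: fit exists there; the LvdT model itself no longer strictly applies).
LVDT_EXTRAPOLATED_FITS: dict[float, LvdTParams] = {
    1.5: LvdTParams(10.0, 0.10),
}

#: target second/first harmonic ratios of the condition suite; the
#: nonlinear response switches on near 0.5 mM, grows to the CMC (1 mM)
#: and levels off above it.
HARMONIC_RATIO_SCHEDULE: dict[float, float] = {
    0.2: 0.0,
    0.5: 0.05,
    0.8: 0.15,
    1.0: 0.30,
    1.5: 0.30,
}

#: approximate equilibrium baseline tensions (mN/m) for the suite conditions
_BASELINE_TENSION: dict[float, float] = {0.2: 48.0, 0.5: 35.0, 0.8: 28.0, 1.0: 25.0, 1.5: 25.0}

SUITE_FREQUENCIES = (0.01, 0.1)


def area_amplitude_from_volume(volume_fraction: float) -> float:
    """Relative area amplitude for a given relative volume amplitude.

    For a near-spherical drop A ~ V^(2/3), so dA/A = (2/3) dV/V.
    """
    return 2.0 / 3.0 * volume_fraction


@dataclass
class TraceRecipe:
    """Everything needed to synthesise one oscillation trace.

    ``modulus`` is the complex dilational modulus (mN/m); alternatively
    give ``lvdt`` parameters and the modulus is evaluated at ``frequency``.
    ``nonlinearity`` is the quadratic distortion coefficient beta in
    ``beta * (a*sin(2*pi*nu*t))^2`` (mN/m), producing a second harmonic of
    amplitude ``beta*a^2/2``. ``noise_sd`` defaults to the instrument's
    0.1 mN/m tension precision.
    """

    frequency: float
    modulus: complex | None = None
    lvdt: LvdTParams | None = None
    amplitude_fraction: float = 0.1
    mean_area: float = 25.0  # mm^2, ~11 uL pendant drop
    baseline_tension: float = 40.0  # mN/m
    nonlinearity: float = 0.0
    noise_sd: float = 0.1
    duration_periods: int = 10
    sample_rate: float = 1.0  # Hz, drop profile recorded every second
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modulus is None and self.lvdt is None:
            raise ValueError("give either an explicit modulus or LvdT parameters")
        if not 0.0 < self.amplitude_fraction <= 0.2:
            raise ValueError("amplitude_fraction must be in (0, 0.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_periods < 3:
            raise ValueError("duration_periods must be >= 3")

    def resolve_modulus(self) -> complex:
        if self.modulus is not None:
            return complex(self.modulus)
        return complex(lvdt_modulus(self.lvdt, self.frequency))


def nonlinearity_for_ratio(
    ratio: float, modulus_magnitude: float, amplitude_fraction: float
) -> float:
    """Distortion coefficient beta giving a target second/first harmonic ratio.

    The first tension harmonic has amplitude |eps|*a and the sin^2 term
    contributes a second harmonic of amplitude beta*a^2/2 (from
    sin^2 x = (1 - cos 2x)/2), so beta = 2*ratio*|eps|/a.
    """
    return 2.0 * ratio * modulus_magnitude / amplitude_fraction


def generate_oscillation_trace(recipe: TraceRecipe) -> OscillationTrace:
    """Synthesise one drop-oscillation trace from a recipe.

    Area: ``A(t) = A0 * (1 + a*sin(2*pi*nu*t))``. Tension:
    ``sigma_base + |eps|*a*sin(2*pi*nu*t + phi) + beta*(a*sin(2*pi*nu*t))^2``
    with ``phi = atan2(eps_i, eps_r)``, plus Gaussian noise. Deterministic
    under a fixed seed.
    """
    nu = recipe.frequency
    n = int(round(recipe.duration_periods / nu * recipe.sample_rate)) + 1
    t = np.arange(n, dtype=float) / recipe.sample_rate
    a = recipe.amplitude_fraction
    w = 2.0 * np.pi * nu * t
    area = recipe.mean_area * (1.0 + a * np.sin(w))

    eps = recipe.resolve_modulus()
    phi = math.atan2(eps.imag, eps.real)
    tension = (
        recipe.baseline_tension
        + abs(eps) * a * np.sin(w + phi)
        + recipe.nonlinearity * (a * np.sin(w)) ** 2
    )
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        tension = tension + rng.normal(0.0, recipe.noise_sd, size=n)

    meta = dict(recipe.meta)
    meta.setdefault("frequency_hz", nu)
    return OscillationTrace(
        t=t, area=area, tension=tension, nominal_frequency=nu, meta=meta
    )


def generate_isotherm_dataset(
    system: MixtureSystem,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> IsothermDataset:
    """Surface-tension isotherm sampled from the mixture adsorption model.

    Gaussian tension noise of ``noise_sd`` (mN/m) is added reproducibly
    under a fixed seed; ``noise_sd = 0`` returns the model curve exactly.
    """
    conc = np.asarray(concentrations, dtype=float)
    sigma = surface_tension_curve(system, conc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, size=conc.size)
    return IsothermDataset(
        concentrations=conc,
        tensions=sigma,
        salt_mM=system.salt_mM,
        meta={"noise_sd": noise_sd, "seed": seed},
    )


def lae_reference_system(aged: bool = False, salt_mM: float = 0.0) -> MixtureSystem:
    """Default LAE-like mixture for isotherm simulations.

    Fresh solutions carry 0.2% molar of dodecanoate as a neutral
    LAE-dodecanoate heterodimer; aged (hydrolysed) solutions carry 18%
    molar of lauroyl arginine as a singly charged LAE-LAS heterodimer. The
    heterodimer is far more surface-active than the monomer, which is what
    pulls the tension at the CMC down to ~25 mN/m.
    """
    monomer = SurfactantComponent(
        name="LAE", charge=+1, surface_activity=30.0, molar_area=2.5e5,
        interaction=(1.0, 1.0),
    )
    if aged:
        dimer = SurfactantComponent(
            name="LAE-LAS", charge=+1, surface_activity=2.0e4, molar_area=4.0e5,
            interaction=(1.0, 1.0),
        )
        fraction = 0.18
    else:
        dimer = SurfactantComponent(
            name="LAE-DDA", charge=0, surface_activity=2.0e4, molar_area=4.0e5,
            interaction=(1.0, 1.0),
        )
        fraction = 0.002
    return MixtureSystem(
        components=[monomer, dimer],
        minority_fraction=fraction,
        salt_mM=salt_mM,
        cmc_mM=1.05,
    )


def reference_condition_suite(out_dir, seed: int = 0) -> list[Path]:
    """Write the standard condition grid of trace CSVs.

    One file per (concentration, frequency) pair over 0.2-1.5 mM at 0.01
    and 0.1 Hz, using the reference LvdT parameters below the CMC and the
    flagged extrapolation above it, with the quadratic distortion ramping
    up from its ~0.5 mM onset. Returns the written paths.
    """
    from .io import write_trace_csv  # deferred: io imports trace types

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**LVDT_REFERENCE_FITS, **LVDT_EXTRAPOLATED_FITS}
    amplitude = area_amplitude_from_volume(0.1)
    paths = []
    for i, conc in enumerate(sorted(HARMONIC_RATIO_SCHEDULE)):
        for j, freq in enumerate(SUITE_FREQUENCIES):
            lvdt = params[conc]
            eps = lvdt_modulus(lvdt, freq)
            ratio = HARMONIC_RATIO_SCHEDULE[conc]
            recipe = TraceRecipe(
                frequency=freq,
                lvdt=lvdt,
                amplitude_fraction=amplitude,
                baseline_tension=_BASELINE_TENSION[conc],
                nonlinearity=nonlinearity_for_ratio(ratio, abs(eps), amplitude),
                seed=seed + 10 * i + j,
                meta={
                    "concentration_mM": conc,
                    "frequency_hz": freq,
                    "lvdt_extrapolated": conc in LVDT_EXTRAPOLATED_FITS,
                    "seed": seed + 10 * i + j,
                },
            )
            trace = generate_oscillation_trace(recipe)
            path = out / f"trace_{conc:g}mM_{freq:g}Hz.csv"
            write_trace_csv(trace, path)
            paths.append(path)
    return paths


def frequency_sweep_suite(
    out_dir,
    concentrations=None,
    frequencies=None,
    seed: int = 0,
    duration_periods: int = 10,
) -> list[Path]:
    """Write per-concentration frequency sweeps suitable for LvdT fitting.

    Defaults: the five reference concentrations at 7 log-spaced
    frequencies in [0.01, 0.2] Hz (the instrument's oscillation band),
    with the same distortion schedule as the condition suite and a sample
    rate oversampled to 20 points per period at the highest frequency.
    """
    from .io import write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**LVDT_REFERENCE_FITS, **LVDT_EXTRAPOLATED_FITS}
    if concentrations is None:
        concentrations = sorted(HARMONIC_RATIO_SCHEDULE)
    if frequencies is None:
        frequencies = np.logspace(np.log10(0.01), np.log10(0.2), 7)
    amplitude = area_amplitude_from_volume(0.1)
    paths = []
    idx = 0
    for conc in concentrations:
        lvdt = params[conc]
        ratio = HARMONIC_RATIO_SCHEDULE.get(conc, 0.0)
        for freq in frequencies:
            eps = lvdt_modulus(lvdt, freq)
            recipe = TraceRecipe(
                frequency=float(freq),
                lvdt=lvdt,
                amplitude_fraction=amplitude,
                baseline_tension=_BASELINE_TENSION.get(conc, 40.0),
                nonlinearity=nonlinearity_for_ratio(ratio, abs(eps), amplitude),
                duration_periods=duration_periods,
                sample_rate=max(1.0, 20.0 * float(freq)),
                seed=seed + idx,
                meta={
                    "concentration_mM": conc,
                    "frequency_hz": float(freq),
                    "lvdt_extrapolated": conc in LVDT_EXTRAPOLATED_FITS,
                    "seed": seed + idx,
                },
            )
            trace = generate_oscillation_trace(recipe)
            path = out / f"sweep_{conc:g}mM_{freq:.4g}Hz.csv"
            write_trace_csv(trace, path)
            paths.append(path)
            idx += 1
    return paths
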