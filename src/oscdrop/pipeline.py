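"""End-to-end pipeline: simulate -> analyze -> fit, with a run manifest.

The :class:`RunConfig` schema is strict (unknown keys are rejected before
any stage runs) and every physical parameter is bounds-checked. Outputs
are deterministic for a fixed config: rerunning writes byte-identical
numeric files. The manifest records package/library versions, every seed
used, the effective parameters and the produced files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .io import read_trace_csv, write_modulus_table
from .lvdt import fit_lvdt
from .modulus import ModulusSpectrum, SmoothingConfig, dilational_modulus


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = Field(default=0, ge=0, lt=2**31)
    # "sweep": per-concentration frequency sweeps (fittable by LvdT);
    # "conditions": the two-frequency reference condition grid.
    kind: str = Field(default="sweep", pattern="^(sweep|conditions)$")
    n_frequencies: int = Field(default=7, ge=3, le=25)


class AnalyzeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    span_periods: float = Field(default=0.3, gt=0.0, le=2.0)
    degree: int = Field(default=2, ge=0, le=4)
    n_harmonics: int = Field(default=4, ge=2, le=8)
    smoothed: bool = True
    refine_frequency: bool = True


class LvdTFitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    part: str = Field(default="real", pattern="^(real|complex)$")


class RunConfig(BaseModel):
    """Top-level pipeline configuration (strict: unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "oscdrop_run"
    log_level: str = Field(default="INFO", pattern="^(DEBUG|INFO|WARNING|ERROR)$")
    simulate: SimulateConfig = SimulateConfig()
    analyze: AnalyzeConfig = AnalyzeConfig()
    lvdt_fit: LvdTFitConfig = LvdTFitConfig()


def analyze_traces(paths, cfg: AnalyzeConfig) -> list:
    """Analyse trace CSVs into modulus points (order preserved)."""
    smoothing = SmoothingConfig(
        enabled=cfg.smoothed, span_periods=cfg.span_periods, degree=cfg.degree
    )
    points = []
    for path in paths:
        trace = read_trace_csv(path)
        points.append(
            dilational_modulus(
                trace,
                smoothing=smoothing,
                n_harmonics=cfg.n_harmonics,
                refine=cfg.refine_frequency,
            )
        )
    return points


def lvdt_table(points, part: str = "real") -> pd.DataFrame:
    """Fit the LvdT model per concentration group of modulus points."""
    rows = []
    by_conc: dict = {}
    for p in points:
        if p.quality_flag != "ok":
            continue  # below-noise-floor points carry no modulus information
        by_conc.setdefault(p.meta.get("concentration_mM"), []).append(p)
    for conc in sorted(k for k in by_conc if k is not None):
        group = sorted(by_conc[conc], key=lambda p: p.frequency)
        if len({round(p.frequency, 12) for p in group}) < 3:
            continue  # cannot constrain a 2-parameter fit
        spectrum = ModulusSpectrum(points=group, meta={"concentration_mM": conc})
        fit = fit_lvdt(spectrum, part=part)
        rows.append(
            {
                "concentration_mM": conc,
                "eps0_mN_m": fit.params.gibbs_elasticity,
                "nuD_hz": fit.params.diffusion_frequency,
                "eps0_sd": fit.param_uncertainty[0],
                "nuD_sd": fit.param_uncertainty[1],
                "residual_rms": fit.residual_rms,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute simulate -> analyze -> fit and write tables plus a manifest.

    Returns the manifest dict; hard stage failures raise, partial results
    are flagged in the manifest's ``stages`` block.
    """
    from .synthetic import frequency_sweep_suite, reference_condition_suite

    if isinstance(config, dict):
        config = RunConfig.model_validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "versions": {
            "oscdrop": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": config.model_dump(),
        "seeds": {"master": config.simulate.seed},
        "stages": {},
        "outputs": [],
    }

    trace_dir = out / "traces"
    if config.simulate.kind == "conditions":
        paths = reference_condition_suite(trace_dir, seed=config.simulate.seed)
    else:
        freqs = np.logspace(np.log10(0.01), np.log10(0.2), config.simulate.n_frequencies)
        paths = frequency_sweep_suite(
            trace_dir, frequencies=freqs, seed=config.simulate.seed
        )
    manifest["seeds"]["traces"] = {
        p.name: read_trace_csv(p).meta.get("seed") for p in paths
    }
    manifest["stages"]["simulate"] = {"status": "ok", "n_files": len(paths)}
    manifest["outputs"] += [str(p) for p in paths]

    points = analyze_traces(paths, config.analyze)
    modulus_path = out / "modulus.csv"
    write_modulus_table(points, modulus_path)
    ratio_path = out / "harmonic_ratio.csv"
    pd.DataFrame(
        {
            "concentration_mM": [p.meta.get("concentration_mM") for p in points],
            "frequency_hz": [p.frequency for p in points],
            "ratio": [p.harmonic_ratio for p in points],
        }
    ).to_csv(ratio_path, index=False, float_format="%.17g")
    manifest["stages"]["analyze"] = {"status": "ok", "n_points": len(points)}
    manifest["outputs"] += [str(modulus_path), str(ratio_path)]

    fits = lvdt_table(points, part=config.lvdt_fit.part)
    fit_path = out / "lvdt_fits.csv"
    fits.to_csv(fit_path, index=False, float_format="%.17g")
    manifest["stages"]["fit_lvdt"] = {"status": "ok", "n_fits": len(fits)}
    manifest["outputs"].append(str(fit_path))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"].append(str(manifest_path))
    return manifest
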