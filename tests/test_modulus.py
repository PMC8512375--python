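"""Dilational modulus extraction: phase conventions, round trips, ratios."""

import numpy as np
import pytest

from oscdrop import (
    OscillationTrace,
    SmoothingConfig,
    TraceRecipe,
    dilational_modulus,
    generate_oscillation_trace,
    harmonic_ratio_curve,
    nonlinearity_for_ratio,
)
from oscdrop.errors import NoExcitationError


def _trace(eps, nu=0.05, a=0.1, phase_offset=None, noise=0.0, seed=None):
    recipe = TraceRecipe(
        frequency=nu,
        modulus=eps,
        amplitude_fraction=a,
        noise_sd=noise,
        duration_periods=10,
        sample_rate=2.0,
        seed=seed,
    )
    return generate_oscillation_trace(recipe)


def test_purely_elastic_in_phase_response():
    point = dilational_modulus(_trace(50.0 + 0.0j))
    assert point.eps_real == pytest.approx(50.0, abs=1e-9)
    assert point.eps_imag == pytest.approx(0.0, abs=1e-9)


def test_purely_viscous_quadrature_response():
    """Tension in phase-quadrature with area gives a purely imaginary
    modulus with eps_i = A0 * a_sigma / |dA1|."""
    nu, a0, a = 0.05, 25.0, 0.1
    t = np.arange(0.0, 200.5, 0.5)
    w = 2 * np.pi * nu * t
    area = a0 * (1 + a * np.sin(w))
    amp_sigma = 1.2
    tension = 40.0 + amp_sigma * np.sin(w + np.pi / 2)
    trace = OscillationTrace(t, area, tension, nu)
    point = dilational_modulus(trace)
    assert point.eps_real == pytest.approx(0.0, abs=1e-9)
    assert point.eps_imag == pytest.approx(a0 * amp_sigma / (a0 * a), abs=1e-9)


def test_noiseless_round_trip_is_exact(linear_trace):
    trace, eps = linear_trace
    point = dilational_modulus(trace)
    assert abs(point.eps - eps) < 1e-9
    assert point.mean_area == pytest.approx(25.0, abs=1e-9)


def test_round_trip_with_and_without_smoothing_agree(linear_trace):
    trace, eps = linear_trace
    p_smooth = dilational_modulus(trace, smoothing=SmoothingConfig(enabled=True))
    p_raw = dilational_modulus(trace, smoothing=SmoothingConfig(enabled=False))
    assert abs(p_smooth.eps - p_raw.eps) < 1e-9


def test_noisy_round_trip_within_half_unit():
    point = dilational_modulus(_trace(30.0 + 10.0j, noise=0.1, seed=7))
    assert point.eps_real == pytest.approx(30.0, abs=0.5)
    assert point.eps_imag == pytest.approx(10.0, abs=0.5)


def test_modulus_scales_linearly_with_tension_amplitude():
    p1 = dilational_modulus(_trace(20.0 + 5.0j))
    p2 = dilational_modulus(_trace(3.0 * (20.0 + 5.0j)))
    assert abs(p2.eps) == pytest.approx(3.0 * abs(p1.eps), rel=1e-9)
    assert p2.harmonic_ratio == pytest.approx(p1.harmonic_ratio, abs=1e-9)


def test_time_origin_shift_preserves_modulus(linear_trace):
    trace, eps = linear_trace
    shifted = OscillationTrace(
        trace.t + 123.4, trace.area, trace.tension, trace.nominal_frequency
    )
    p = dilational_modulus(shifted)
    assert abs(p.eps - eps) < 1e-8


def test_no_excitation_below_floor_raises():
    nu = 0.05
    t = np.arange(0.0, 200.5, 0.5)
    area = np.full_like(t, 25.0)  # no oscillation at all
    tension = 40.0 + 0.5 * np.sin(2 * np.pi * nu * t)
    with pytest.raises(NoExcitationError):
        dilational_modulus(OscillationTrace(t, area, tension, nu))


def test_flat_tension_flags_no_response():
    nu = 0.05
    t = np.arange(0.0, 200.5, 0.5)
    area = 25.0 * (1 + 0.1 * np.sin(2 * np.pi * nu * t))
    tension = np.full_like(t, 40.0)
    point = dilational_modulus(OscillationTrace(t, area, tension, nu))
    assert point.quality_flag == "no_response"
    assert point.eps_real == 0.0 and point.eps_imag == 0.0


def test_linear_response_has_zero_harmonic_ratio(linear_trace):
    trace, _ = linear_trace
    point = dilational_modulus(trace)
    assert point.harmonic_ratio < 1e-9


def test_harmonic_ratio_invariant_to_tension_offset(linear_trace):
    trace, _ = linear_trace
    shifted = OscillationTrace(
        trace.t, trace.area, trace.tension + 7.7, trace.nominal_frequency
    )
    p0 = dilational_modulus(trace)
    p1 = dilational_modulus(shifted)
    assert p1.harmonic_ratio == pytest.approx(p0.harmonic_ratio, abs=1e-9)


def test_harmonic_ratio_curve_tracks_injected_distortion():
    eps = 30.0 + 10.0j
    a = 0.1
    traces = []
    for conc, ratio in [(0.2, 0.0), (1.0, 0.30)]:
        beta = nonlinearity_for_ratio(ratio, abs(eps), a)
        recipe = TraceRecipe(
            frequency=0.05,
            modulus=eps,
            amplitude_fraction=a,
            nonlinearity=beta,
            noise_sd=0.0,
            duration_periods=10,
            sample_rate=2.0,
            meta={"concentration_mM": conc},
        )
        traces.append(generate_oscillation_trace(recipe))
    table = harmonic_ratio_curve(traces)
    assert list(table["concentration_mM"]) == [0.2, 1.0]
    assert table["ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert table["ratio"].iloc[1] == pytest.approx(0.30, abs=1e-6)
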