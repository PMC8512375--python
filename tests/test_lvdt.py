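"""LvdT model: analytic limits, parameter ordering, fit recovery."""

import numpy as np
import pytest
from sklearn.base import clone

from oscdrop import LvdTModel, LvdTParams, fit_lvdt, lvdt_modulus
from oscdrop.errors import InsufficientDataError

FREQS = np.logspace(np.log10(0.005), np.log10(0.2), 15)


def test_insoluble_monolayer_limit_is_purely_elastic():
    eps = lvdt_modulus(LvdTParams(42.0, 0.0), 0.05)
    assert eps == pytest.approx(42.0 + 0.0j)


def test_zero_gibbs_elasticity_gives_zero_modulus():
    eps = lvdt_modulus(LvdTParams(0.0, 0.01), FREQS)
    np.testing.assert_allclose(np.abs(eps), 0.0)


def test_xi_equal_one_gives_two_fifths_and_one_fifth():
    # nu = nu_D / 2 makes xi = 1, so eps = eps0 * (2 + i) / 5
    eps0, nu_d = 30.0, 0.1
    eps = lvdt_modulus(LvdTParams(eps0, nu_d), nu_d / 2.0)
    assert eps.real == pytest.approx(0.4 * eps0, rel=1e-12)
    assert eps.imag == pytest.approx(0.2 * eps0, rel=1e-12)


def test_limiting_behaviour_high_and_low_frequency():
    p = LvdTParams(50.0, 0.01)
    hi = lvdt_modulus(p, 1e6)
    lo = lvdt_modulus(p, 1e-9)
    assert hi.real == pytest.approx(50.0, rel=1e-3)
    assert abs(hi.imag) < 0.1
    assert abs(lo) < 0.1


def test_loss_below_storage_below_gibbs_over_parameter_sweep(rng):
    """0 < eps_i < eps_r < eps0 whenever xi > 0 — a measured loss part
    exceeding the storage part falls outside the diffusional model."""
    eps0 = rng.uniform(1.0, 100.0, 100)
    nu_d = 10 ** rng.uniform(-4, 1, 100)
    nu = 10 ** rng.uniform(-3, 0, 100)
    for i in range(100):
        eps = lvdt_modulus(LvdTParams(eps0[i], nu_d[i]), nu)
        assert np.all(eps.imag > 0)
        assert np.all(eps.imag < eps.real)
        assert np.all(eps.real < eps0[i])


def test_storage_increases_with_frequency_loss_has_single_peak():
    p = LvdTParams(40.0, 0.02)
    nu = np.logspace(-4, 1, 300)
    eps = lvdt_modulus(p, nu)
    assert np.all(np.diff(eps.real) > 0)
    sign_changes = np.sum(np.diff(np.sign(np.diff(eps.imag))) != 0)
    assert sign_changes == 1


def test_phase_angle_below_45_degrees():
    p = LvdTParams(40.0, 0.05)
    nu = np.logspace(-3, 0, 50)
    eps = lvdt_modulus(p, nu)
    phase = np.arctan2(eps.imag, eps.real)
    assert np.all((phase >= 0) & (phase < np.pi / 4))


@pytest.mark.parametrize(
    "eps0,nu_d",
    [(30.1, 0.0032), (73.9, 0.02), (45.3, 0.0081), (26.9, 0.03), (12.6, 0.06)],
)
def test_noiseless_fit_recovers_generating_parameters(eps0, nu_d):
    y = lvdt_modulus(LvdTParams(eps0, nu_d), FREQS).real
    model = LvdTModel(part="real").fit(FREQS, y)
    assert model.eps0_ == pytest.approx(eps0, rel=1e-3)
    assert model.nu_d_ == pytest.approx(nu_d, rel=1e-3)


def test_complex_joint_fit_recovers_parameters():
    y = lvdt_modulus(LvdTParams(33.0, 0.015), FREQS)
    model = LvdTModel(part="complex").fit(FREQS, y)
    assert model.eps0_ == pytest.approx(33.0, rel=1e-3)
    assert model.nu_d_ == pytest.approx(0.015, rel=1e-3)


def test_constant_spectrum_drives_nu_d_to_its_bound():
    y = np.full(FREQS.size, 27.0)
    model = LvdTModel().fit(FREQS, y)
    assert model.eps0_ == pytest.approx(27.0, rel=1e-3)
    assert model.nu_d_ < 1e-6


def test_fit_idempotence_from_fitted_optimum():
    y = lvdt_modulus(LvdTParams(45.3, 0.0081), FREQS).real
    first = LvdTModel().fit(FREQS, y)
    again = LvdTModel(
        starts_eps0=(first.eps0_,), starts_nud=(first.nu_d_,)
    ).fit(FREQS, y)
    assert again.eps0_ == pytest.approx(first.eps0_, rel=1e-9)
    assert again.nu_d_ == pytest.approx(first.nu_d_, rel=1e-6)


def test_monte_carlo_mean_recovery_under_noise(rng):
    """Noisy replicates (sd 1 mN/m on eps_r) recover the generating
    parameters within 5% on average."""
    eps0, nu_d = 45.3, 0.0081
    clean = lvdt_modulus(LvdTParams(eps0, nu_d), FREQS).real
    rec = np.array(
        [
            (m.eps0_, m.nu_d_)
            for m in (
                LvdTModel().fit(FREQS, clean + rng.normal(0, 1.0, FREQS.size))
                for _ in range(200)
            )
        ]
    )
    assert rec[:, 0].mean() == pytest.approx(eps0, rel=0.05)
    assert rec[:, 1].mean() == pytest.approx(nu_d, rel=0.05)


def test_too_few_frequencies_raise():
    with pytest.raises(InsufficientDataError):
        LvdTModel().fit([0.01, 0.1], [10.0, 20.0])


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        lvdt_modulus(LvdTParams(10.0, 0.01), -0.1)


def test_estimator_is_sklearn_cloneable_and_wrapper_agrees():
    model = LvdTModel(part="real")
    cloned = clone(model)
    assert cloned.get_params() == model.get_params()
    y = lvdt_modulus(LvdTParams(30.1, 0.0032), FREQS).real
    fit = fit_lvdt((FREQS, y))
    m = model.fit(FREQS, y)
    assert fit.params.gibbs_elasticity == pytest.approx(m.eps0_)
    assert fit.converged
    np.testing.assert_allclose(m.predict(FREQS), y, atol=1e-8)
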