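"""Adsorption model: closed-form limits, electrostatics, fit recovery."""

from dataclasses import replace

import numpy as np
import pytest

from oscdrop import (
    MixtureSystem,
    SurfactantComponent,
    bulk_speciation,
    equilibrium_coverage,
    fit_isotherm,
    generate_isotherm_dataset,
    lae_reference_system,
    surface_tension,
    surface_tension_curve,
)
from oscdrop.errors import InsufficientDataError
from oscdrop.isotherm import R_GAS, MixedIsothermModel

B, OMEGA = 5.0, 2.5e5  # m^3/mol, m^2/mol
SIGMA0 = 72.5
RT = R_GAS * 295.0


def neutral_system(b=B, omega=OMEGA, a=0.0):
    comp = SurfactantComponent("X", 0, b, omega, (a,))
    return MixtureSystem(components=[comp])


def szyszkowski(c_mol_per_L, b=B, omega=OMEGA):
    # closed-form oracle: sigma0 - sigma = (RT/omega) ln(1 + b c), SI units
    return SIGMA0 - (RT / omega) * np.log1p(b * 1000.0 * c_mol_per_L) * 1000.0


class TestSpeciation:
    def test_no_minority_species_is_single_component(self):
        sp = bulk_speciation(neutral_system(), 1e-3)
        assert sp.component_concentrations == {"X": 1e-3}

    def test_minority_fraction_splits_18_percent(self):
        sp = bulk_speciation(lae_reference_system(aged=True), 1e-3)
        assert sp.component_concentrations["LAE-LAS"] == pytest.approx(0.18e-3)
        assert sp.component_concentrations["LAE"] == pytest.approx(0.82e-3)

    @pytest.mark.parametrize("salt", [0.0, 10.0, 100.0])
    @pytest.mark.parametrize("aged", [False, True])
    def test_bulk_electroneutrality(self, salt, aged):
        system = lae_reference_system(aged=aged, salt_mM=salt)
        sp = bulk_speciation(system, 5e-4)
        assert sp.charge_balance == pytest.approx(0.0, abs=1e-18)

    def test_ionic_strength_includes_salt(self):
        s0 = bulk_speciation(lae_reference_system(salt_mM=0.0), 1e-3)
        s1 = bulk_speciation(lae_reference_system(salt_mM=100.0), 1e-3)
        assert s1.ionic_strength == pytest.approx(s0.ionic_strength + 0.1)


class TestEquilibrium:
    def test_clean_interface_at_zero_concentration(self):
        system = neutral_system()
        state = equilibrium_coverage(system, bulk_speciation(system, 0.0))
        assert state.total_coverage == 0.0
        assert state.surface_pressure == 0.0
        assert state.surface_potential == 0.0

    def test_langmuir_closed_form(self):
        system = neutral_system()
        state = equilibrium_coverage(system, bulk_speciation(system, 1e-3))
        bc = B * 1.0  # 1e-3 mol/dm^3 = 1 mol/m^3
        assert state.coverages["X"] == pytest.approx(bc / (1 + bc), abs=1e-10)

    def test_identical_neutral_components_share_coverage(self):
        comps = [
            SurfactantComponent("A", 0, B, OMEGA),
            SurfactantComponent("B", 0, B, OMEGA),
        ]
        system = MixtureSystem(components=comps, minority_fraction=0.5)
        state = equilibrium_coverage(system, bulk_speciation(system, 1e-3))
        assert state.coverages["A"] == pytest.approx(state.coverages["B"], rel=1e-12)

    def test_charged_layer_develops_positive_potential(self):
        system = MixtureSystem(components=[SurfactantComponent("C", 1, B, OMEGA)])
        state = equilibrium_coverage(system, bulk_speciation(system, 1e-3))
        assert state.surface_potential > 0.0
        assert state.residual < 1e-10


class TestSurfaceTension:
    def test_pure_solvent(self):
        assert surface_tension(neutral_system(), 0.0) == SIGMA0

    def test_szyszkowski_equation_over_grid(self):
        grid = np.logspace(-5, -2, 50)
        model = surface_tension_curve(neutral_system(), grid)
        oracle = szyszkowski(grid)
        np.testing.assert_allclose(model, oracle, rtol=1e-8)

    def test_monotone_decreasing_in_concentration(self):
        system = lae_reference_system()
        grid = np.logspace(-5.5, -2.5, 50)
        sigma = surface_tension_curve(system, grid)
        assert np.all(np.diff(sigma) <= 1e-10)

    def test_salt_screening_lowers_ionic_surfactant_tension(self):
        plain = MixtureSystem(components=[SurfactantComponent("C", 1, B, OMEGA)])
        salted = MixtureSystem(
            components=[SurfactantComponent("C", 1, B, OMEGA)], salt_mM=100.0
        )
        grid = np.logspace(-5, -2.5, 30)
        np.testing.assert_array_less(
            surface_tension_curve(salted, grid) - 1e-10,
            surface_tension_curve(plain, grid),
        )

    def test_flat_branch_above_configured_cmc(self):
        system = lae_reference_system()
        at_cmc = surface_tension(system, system.cmc_mM / 1000.0)
        assert surface_tension(system, 5e-3) == pytest.approx(at_cmc, abs=1e-10)

    def test_gibbs_adsorption_consistency_at_mid_coverage(self):
        """Surface excess from -dsigma/d(RT ln c) matches theta/omega."""
        system = neutral_system()
        c0, h = 2e-4, 1e-3
        ds = (
            surface_tension(system, c0 * np.exp(h))
            - surface_tension(system, c0 * np.exp(-h))
        ) / (2 * h)
        gamma_numeric = -ds / 1000.0 / RT  # mol/m^2
        theta = equilibrium_coverage(system, bulk_speciation(system, c0)).coverages["X"]
        assert gamma_numeric == pytest.approx(theta / OMEGA, rel=0.01)

    def test_gibbs_consistency_with_frumkin_interaction(self):
        system = neutral_system(a=1.0)
        c0, h = 1.5e-4, 1e-3
        ds = (
            surface_tension(system, c0 * np.exp(h))
            - surface_tension(system, c0 * np.exp(-h))
        ) / (2 * h)
        gamma_numeric = -ds / 1000.0 / RT
        theta = equilibrium_coverage(system, bulk_speciation(system, c0)).coverages["X"]
        assert gamma_numeric == pytest.approx(theta / OMEGA, rel=0.01)


class TestFit:
    def test_szyszkowski_round_trip_free_b_omega(self):
        data = generate_isotherm_dataset(neutral_system(), np.logspace(-5, -2.5, 25))
        start = MixtureSystem(components=[SurfactantComponent("X", 0, 1.0, 1.5e5)])
        fitted, resid = fit_isotherm(data, start, ["b:X", "omega:X"])
        assert fitted.components[0].surface_activity == pytest.approx(B, rel=0.01)
        assert fitted.components[0].molar_area == pytest.approx(OMEGA, rel=0.01)
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_two_component_round_trip_with_frozen_fraction(self):
        true = lae_reference_system()  # minority fraction fixed at 0.002
        grid = np.logspace(-5, np.log10(1.0e-3), 20)
        data = generate_isotherm_dataset(true, grid)
        start = true.copy()
        start.components[0] = replace(start.components[0], surface_activity=10.0)
        start.components[1] = replace(start.components[1], surface_activity=5e3)
        fitted, _ = fit_isotherm(data, start, ["b:LAE", "b:LAE-DDA"])
        assert fitted.minority_fraction == 0.002
        for comp, truth in zip(fitted.components, true.components):
            assert comp.surface_activity == pytest.approx(
                truth.surface_activity, rel=0.01
            )

    def test_empty_free_list_returns_template_with_residuals(self):
        system = neutral_system()
        data = generate_isotherm_dataset(system, np.logspace(-5, -2.5, 10))
        model = MixedIsothermModel(system, ()).fit(data.concentrations, data.tensions)
        assert model.system_.components[0].surface_activity == B
        np.testing.assert_allclose(model.residuals_, 0.0, atol=1e-10)

    def test_too_few_points_below_cmc_rejected(self):
        system = lae_reference_system()
        conc = np.array([0.5e-3, 0.8e-3, 2e-3, 3e-3, 4e-3, 5e-3])
        sigma = surface_tension_curve(system, conc)
        with pytest.raises(InsufficientDataError):
            MixedIsothermModel(system, ("b:LAE",)).fit(conc, sigma)
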