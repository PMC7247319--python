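import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtide.constants import (
    DEFAULT_EPS_R,
    DEFAULT_TEMPERATURE,
    FARADAY,
    GAS_CONSTANT,
    VACUUM_PERMITTIVITY,
)
from memtide.gcs import (
    ElectrolyteComposition,
    Ion,
    _decay_residual,
    _thermal_voltage,
    debye_constant,
    divalent_accumulation_ratio,
    grahame_sigma,
    peptide_modified_sigma,
    potential_profile,
    solve_surface_potential,
    surface_potential_from_zeta,
    zeta_from_mobility,
)
from memtide.membranes import intrinsic_surface_charge_density, mean_lipid_area


class TestElectrolyte:
    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutrality"):
            ElectrolyteComposition((Ion("K", 1, 0.1), Ion("Cl", -1, 0.05)))

    def test_with_ion_rebalances(self, calcium_electrolyte):
        updated = calcium_electrolyte.with_ion("Ca", 10e-6)
        net = sum(i.valence * i.conc for i in updated.ions)
        assert abs(net) < 1e-15
        ca = next(i for i in updated.ions if i.name == "Ca")
        assert ca.conc == 10e-6

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError):
            Ion("K", 1, -0.1)


class TestDebyeConstant:
    def test_100mM_1_1(self, kcl_100mM):
        assert 1e9 / debye_constant(kcl_100mM) == pytest.approx(0.96, abs=0.01)

    def test_20mM_1_1(self, kcl_20mM):
        assert 1e9 / debye_constant(kcl_20mM) == pytest.approx(2.15, abs=0.01)

    def test_quadrupling_halves_length(self, kcl_100mM):
        quad = ElectrolyteComposition.symmetric(0.400)
        assert debye_constant(quad) == pytest.approx(
            2 * debye_constant(kcl_100mM), rel=1e-12
        )

    def test_matches_symmetric_closed_form(self, kcl_100mM):
        # kappa^2 = 2 Z^2 F^2 C / (eps_r eps_0 R T)
        expected = math.sqrt(
            2 * FARADAY**2 * 100.0
            / (DEFAULT_EPS_R * VACUUM_PERMITTIVITY * GAS_CONSTANT
               * DEFAULT_TEMPERATURE)
        )
        assert debye_constant(kcl_100mM) == pytest.approx(expected, rel=1e-12)

    def test_zero_ionic_strength(self):
        empty = ElectrolyteComposition((Ion("K", 1, 0.0), Ion("Cl", -1, 0.0)))
        with pytest.raises(ValueError, match="ionic strength"):
            debye_constant(empty)


class TestGrahame:
    def test_zero_potential(self, kcl_100mM):
        assert grahame_sigma(0.0, kcl_100mM) == 0.0

    def test_debye_huckel_limit(self, kcl_100mM):
        # small psi: sigma ~ eps kappa psi within 2%
        psi = -0.010
        kappa = debye_constant(kcl_100mM)
        linear = DEFAULT_EPS_R * VACUUM_PERMITTIVITY * kappa * psi
        assert grahame_sigma(psi, kcl_100mM) == pytest.approx(linear, rel=0.02)

    @pytest.mark.parametrize("conc", [0.005, 0.02, 0.1, 0.5])
    def test_debye_huckel_limit_across_concs(self, conc):
        elec = ElectrolyteComposition.symmetric(conc)
        kappa = debye_constant(elec)
        for psi in (-0.010, -0.005, 0.005, 0.010):
            linear = DEFAULT_EPS_R * VACUUM_PERMITTIVITY * kappa * psi
            assert grahame_sigma(psi, elec) == pytest.approx(linear, rel=0.02)

    @given(psi=st.floats(0.001, 0.2))
    @settings(max_examples=50)
    def test_antisymmetry(self, psi):
        elec = ElectrolyteComposition.symmetric(0.05)
        assert grahame_sigma(-psi, elec) == pytest.approx(
            -grahame_sigma(psi, elec), rel=1e-12
        )


class TestSolveSurfacePotential:
    def test_tocl_20mM_no_stern(self, tocl_membrane, kcl_20mM):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, kcl_20mM)
        assert state.psi_0 * 1e3 == pytest.approx(-116, abs=1.0)

    def test_fixed_point_roundtrip(self, tocl_membrane):
        elec = ElectrolyteComposition.symmetric(0.02, stern_k_cation=0.6)
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, elec)
        back = grahame_sigma(state.psi_0, elec)
        assert abs(back - state.sigma) < 1e-9

    def test_zero_charge(self, kcl_20mM):
        state = solve_surface_potential(0.0, kcl_20mM)
        assert state.psi_0 == 0.0
        assert state.sigma == 0.0

    def test_salt_screening_monotonic(self, tocl_membrane):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        psis = []
        for conc in (0.005, 0.01, 0.02, 0.05, 0.1, 0.3):
            elec = ElectrolyteComposition.symmetric(conc)
            psis.append(abs(solve_surface_potential(sigma_max, elec).psi_0))
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_stern_adsorption_reduces_magnitude(self, tocl_membrane):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        bare = solve_surface_potential(
            sigma_max, ElectrolyteComposition.symmetric(0.02)
        )
        stern = solve_surface_potential(
            sigma_max,
            ElectrolyteComposition.symmetric(0.02, stern_k_cation=0.6),
        )
        assert abs(stern.psi_0) < abs(bare.psi_0)


class TestPeptideModifiedSigma:
    def test_zero_occupancy_identity(self):
        sigma, engaged = peptide_modified_sigma(-0.0781, 0.0, 6.9, 82.0)
        assert sigma == -0.0781
        assert not engaged

    def test_full_occupancy_delta(self):
        # +3e / 565.8 A^2 = +0.0849 C/m^2, overshooting |sigma_lipid|
        sigma, engaged = peptide_modified_sigma(
            -0.0781, 1.0, 6.9, 82.0, floor_psi=None
        )
        delta = sigma - (-0.0781)
        assert delta == pytest.approx(0.0849, abs=2e-4)
        assert sigma > 0  # sign reversal permitted with floor disabled
        assert not engaged

    def test_floor_engages(self, kcl_20mM):
        sigma, engaged = peptide_modified_sigma(
            -0.0781, 1.0, 6.9, 82.0,
            floor_psi=-0.030, electrolyte=kcl_20mM,
        )
        assert engaged
        state = solve_surface_potential(sigma, kcl_20mM)
        assert state.psi_0 * 1e3 == pytest.approx(-30.0, abs=0.5)

    def test_occupancy_validated(self):
        with pytest.raises(ValueError):
            peptide_modified_sigma(-0.05, 1.5, 6.9, 82.0)


class TestZetaConversions:
    def test_zero_mobility(self):
        assert zeta_from_mobility(0.0) == 0.0

    def test_linearity(self):
        assert zeta_from_mobility(-2e-8) == pytest.approx(
            2 * zeta_from_mobility(-1e-8)
        )

    def test_worked_example(self):
        zeta = zeta_from_mobility(-2.0e-8, 0.89e-3, 78.5)
        assert zeta * 1e3 == pytest.approx(-25.6, abs=0.1)

    def test_nonpositive_viscosity(self):
        with pytest.raises(ValueError):
            zeta_from_mobility(1e-8, 0.0)


class TestSurfacePotentialFromZeta:
    def test_x_zero_identity(self, kcl_100mM):
        kappa = debye_constant(kcl_100mM)
        assert surface_potential_from_zeta(-0.030, kappa, x=0.0) == \
            pytest.approx(-0.030, rel=1e-12)

    def test_zero_zeta(self, kcl_100mM):
        assert surface_potential_from_zeta(
            0.0, debye_constant(kcl_100mM)
        ) == 0.0

    def test_forward_inverse_roundtrip(self, kcl_100mM):
        kappa = debye_constant(kcl_100mM)
        zeta, x = -0.030, 2e-10
        psi_0 = surface_potential_from_zeta(zeta, kappa, x=x)
        vt = _thermal_voltage(DEFAULT_TEMPERATURE)
        residual = _decay_residual(psi_0, zeta, kappa, x, 1, vt)
        assert abs(residual) < 1e-12
        assert abs(psi_0) >= abs(zeta)

    def test_small_potential_limit(self, kcl_100mM):
        kappa = debye_constant(kcl_100mM)
        for zeta in (-0.010, -0.005, 0.008):
            psi_0 = surface_potential_from_zeta(zeta, kappa, x=2e-10)
            assert psi_0 == pytest.approx(
                zeta * math.exp(kappa * 2e-10), rel=0.02
            )

    def test_sanity_bound(self, kcl_100mM):
        with pytest.raises(ValueError, match="sanity"):
            surface_potential_from_zeta(-0.31, debye_constant(kcl_100mM))


class TestPotentialProfile:
    def test_boundary_conditions(self, tocl_membrane, kcl_100mM):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, kcl_100mM)
        x_max = 15.0 / state.kappa
        prof = potential_profile(state, x_max, points=400)
        assert prof.psi_x[0] == pytest.approx(state.psi_0, rel=1e-12)
        assert abs(prof.psi_x[-1]) < 1e-6

    def test_ion_profiles_approach_bulk(self, tocl_membrane, kcl_100mM):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, kcl_100mM)
        prof = potential_profile(state, 15.0 / state.kappa, points=300)
        for ion in kcl_100mM.ions:
            conc = prof.concentrations[ion.name]
            assert conc[-1] == pytest.approx(ion.conc, rel=1e-4)
            assert np.all(conc >= 0)

    def test_analytic_matches_numeric_first_integral(
        self, tocl_membrane, kcl_100mM
    ):
        """Symmetric analytic Gouy solution vs brute-force PB integration."""
        from scipy.integrate import solve_ivp

        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, kcl_100mM)
        x_max = 10.0 / state.kappa
        prof = potential_profile(state, x_max, points=150)

        vt = _thermal_voltage(state.temperature)
        eps = state.eps_r * VACUUM_PERMITTIVITY

        def rhs(_x, y):
            s = sum(
                i.conc * 1e3 * math.expm1(-i.valence * y[0] / vt)
                for i in kcl_100mM.ions
            )
            return [-math.copysign(1.0, state.psi_0) * math.sqrt(
                2 * GAS_CONSTANT * state.temperature / eps * max(s, 0.0)
            )]

        sol = solve_ivp(
            rhs, (0.0, x_max), [state.psi_0], t_eval=prof.x_grid,
            rtol=1e-12, atol=1e-14,
        )
        np.testing.assert_allclose(prof.psi_x, sol.y[0], atol=1e-6)

    def test_mixed_valence_profile_runs(self, calcium_electrolyte,
                                        tocl_membrane):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, calcium_electrolyte)
        prof = potential_profile(state, 10.0 / state.kappa, points=100)
        assert prof.psi_x[0] == pytest.approx(state.psi_0, rel=1e-9)
        assert abs(prof.psi_x[-1]) < 1e-5

    def test_divalent_surface_enhancement(self):
        # at psi_0 = -RT/F (= -25.69 mV), divalent enhancement is e^2
        elec = ElectrolyteComposition((
            Ion("K", 1, 0.1), Ion("Ca", 2, 1e-4), Ion("Cl", -1, 0.1 + 2e-4),
        ))
        vt = _thermal_voltage(DEFAULT_TEMPERATURE)
        sigma = grahame_sigma(-vt, elec)
        state = solve_surface_potential(sigma, elec)
        prof = potential_profile(state, 5e-9, points=50)
        enhancement = prof.concentrations["Ca"][0] / 1e-4
        assert enhancement == pytest.approx(math.e**2, rel=1e-6)


class TestDivalentAccumulationRatio:
    def test_identical_states(self, tocl_membrane, kcl_20mM):
        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        state = solve_surface_potential(sigma_max, kcl_20mM)
        assert divalent_accumulation_ratio(state, state) == 1.0

    def test_exponential_arithmetic(self, tocl_membrane, kcl_20mM):
        from dataclasses import replace

        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        bare = solve_surface_potential(sigma_max, kcl_20mM)
        bound = replace(bare, psi_0=-0.030)
        bare = replace(bare, psi_0=-0.116)
        ratio = divalent_accumulation_ratio(bare, bound)
        vt = _thermal_voltage(DEFAULT_TEMPERATURE)
        assert ratio == pytest.approx(math.exp(2 * 0.086 / vt), rel=1e-9)
        assert ratio > 10

    def test_monotone_in_bare_potential(self, tocl_membrane, kcl_20mM):
        from dataclasses import replace

        sigma_max = intrinsic_surface_charge_density(tocl_membrane)
        ref = solve_surface_potential(sigma_max, kcl_20mM)
        bound = replace(ref, psi_0=-0.030)
        ratios = [
            divalent_accumulation_ratio(replace(ref, psi_0=psi), bound)
            for psi in (-0.05, -0.08, -0.116, -0.15)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
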