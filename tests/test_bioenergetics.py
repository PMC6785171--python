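"""Maintenance law, biomass energy, budgets, thresholds and the Arrhenius fit."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import methanomars as mm
from methanomars.bioenergetics import (
    DEFAULT_CELL_SYNTHESIS_KJ,
    MaintenanceArrheniusModel,
    dissipation_energy_per_molC,
    synthesis_energy_per_gC,
)


class TestMaintenanceLaw:
    @pytest.mark.parametrize(
        "T, expected",
        [(230.0, 1.12e-27), (270.0, 1.39e-16)],
    )
    def test_printed_anchor_values(self, maintenance, T, expected):
        assert mm.maintenance_rate(maintenance, T) == pytest.approx(expected, rel=5e-3, abs=0)

    def test_monotone_in_temperature(self, maintenance):
        temps = np.linspace(180.0, 283.0, 25)
        vals = [mm.maintenance_rate(maintenance, t) for t in temps]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_temperature_rejected(self, maintenance):
        with pytest.raises(mm.ThermodynamicDomainError):
            mm.maintenance_rate(maintenance, -5.0)


class TestBiomassEnergy:
    def test_methane_cell_cost(self):
        """CH4 (C=1, γ=8), 12 fg-C: ~1.09e-12 kJ per cell, matching an
        independent arithmetic evaluation of the dissipation correlation."""
        y = mm.biomass_synthesis_energy(mm.BiomassEnergyParams())
        expected = (200 + 18 * 5**1.8 + math.exp(4.2**0.32 * 4.0)) / 12.01 * 12e-15
        assert y == pytest.approx(expected, rel=1e-12, abs=0)
        # the printed rounding of the same quantity is 1.086e-12
        assert y == pytest.approx(1.086e-12, rel=2e-3, abs=0)

    def test_glucose_like_source(self):
        # C=6: the 18(6-C)^1.8 term vanishes
        got = dissipation_energy_per_molC(6, 4.0)
        expected = 200.0 + math.exp(abs(3.8 - 4.0) ** 0.32 * (3.6 + 2.4))
        assert got == pytest.approx(expected, rel=1e-12, abs=0)

    def test_linear_in_cell_carbon(self):
        y1 = mm.biomass_synthesis_energy(mm.BiomassEnergyParams(cell_carbon=12.0))
        y2 = mm.biomass_synthesis_energy(mm.BiomassEnergyParams(cell_carbon=24.0))
        assert y2 == pytest.approx(2.0 * y1, rel=1e-14, abs=0)

    def test_invalid_params(self):
        with pytest.raises(mm.ConfigurationError):
            mm.BiomassEnergyParams(carbon_atoms=0)
        with pytest.raises(mm.ConfigurationError):
            mm.BiomassEnergyParams(degree_of_reduction=9.0)


class TestEnergyBudget:
    def test_internal_identities(self, lr1, mars_atm):
        b = mm.energy_budget(lr1, mars_atm)
        assert b.power_supply == pytest.approx(-b.rate_r * b.drG, abs=0.0)
        assert b.net_gain == pytest.approx(b.power_supply - b.maintenance, abs=0.0)
        assert math.isfinite(b.doubling_time_yr) == (b.net_gain > 0)

    def test_lr1_viable_at_cold_mars(self, lr1, mars_atm):
        b = mm.energy_budget(lr1, mars_atm)
        assert b.net_gain > 0

    def test_lr1_doubling_time_exceeds_ensemble_minimum(self, lr1, mars_atm):
        b = mm.energy_budget(lr1, mars_atm)
        assert b.doubling_time_yr >= 4831.0

    def test_zero_rate_gives_negative_gain_and_infinite_doubling(self, maintenance):
        assert mm.doubling_time_years(DEFAULT_CELL_SYNTHESIS_KJ, -1e-30) == math.inf
        assert mm.doubling_time_years(DEFAULT_CELL_SYNTHESIS_KJ, 0.0) == math.inf

    def test_doubling_time_diverges_towards_threshold(self, lr1, mars_atm, maintenance):
        thr = mm.minimum_ch4_threshold(lr1, mars_atm, maintenance)
        times = []
        for mult in (1.1, 1.01, 1.0001):
            atm = mars_atm.with_ch4(thr * 1e-9 * mult)
            times.append(mm.energy_budget(lr1, atm, maintenance).doubling_time_yr)
        assert all(math.isfinite(t) for t in times)
        assert times[0] < times[1] < times[2]
        assert times[2] > 100 * times[0]


class TestThreshold:
    def test_zero_maintenance_gives_zero_threshold(self, lr1, mars_atm):
        free = mm.MaintenanceModel(prefactor=1e-300)
        assert mm.minimum_ch4_threshold(lr1, mars_atm, free) == pytest.approx(0.0, abs=1e-12)

    def test_lr1_threshold_inside_printed_envelope(self, lr1, mars_atm, maintenance):
        thr = mm.minimum_ch4_threshold(lr1, mars_atm, maintenance)
        assert 6.24e-8 <= thr <= 9.18e-6

    def test_fixed_point_matches_bisection_oracle(self, mars_atm, maintenance):
        """On 20 random strains the fixed point agrees with a bisection root
        of the full net-gain equation to 1e-6 relative."""
        species = mm.default_species_table()
        strains = mm.sample_strain_ensemble(mm.StrainEnsembleSpec(n_strains=20, seed=42))

        def net_gain_at(strain, gamma):
            atm = mars_atm.with_ch4(gamma)
            return mm.energy_budget(strain, atm, maintenance, species=species).net_gain

        for strain in strains:
            thr = mm.minimum_ch4_threshold(strain, mars_atm, maintenance, species=species)
            root = brentq(
                lambda g: net_gain_at(strain, g),
                1e-25, 1e-6, xtol=1e-30, rtol=1e-12,
            )
            assert thr == pytest.approx(root / 1e-9, rel=1e-6, abs=0)

    def test_threshold_monotone_in_parameters(self, mars_atm, maintenance):
        """Threshold rises with m_E and K_CH4, falls with v_max (3x3 sweep)."""
        for scale in (1.0, 2.0, 4.0):
            vmaxes = [2e-17, 5e-17, 1.5e-16]
            thrs = [
                mm.minimum_ch4_threshold(
                    mm.StrainKinetics("s", v, 2.5e-6 * scale), mars_atm, maintenance
                )
                for v in vmaxes
            ]
            assert thrs[0] > thrs[1] > thrs[2]  # decreasing in v_max
        for v in (2e-17, 5e-17, 1.5e-16):
            thrs = [
                mm.minimum_ch4_threshold(
                    mm.StrainKinetics("s", v, 2.5e-6 * s), mars_atm, maintenance
                )
                for s in (1.0, 2.0, 4.0)
            ]
            assert thrs[0] < thrs[1] < thrs[2]  # increasing in K_CH4
        big_me = mm.MaintenanceModel(prefactor=1e-14)
        lr1 = mm.lr1_fixture()
        assert mm.minimum_ch4_threshold(lr1, mars_atm, big_me) > mm.minimum_ch4_threshold(
            lr1, mars_atm, mm.MaintenanceModel()
        )

    def test_not_viable_returns_infinity(self, lr1, mars_atm):
        # warm temperature + huge maintenance: even saturating CH4 cannot pay
        hot = mm.mars_default_atmosphere(280.0, 6.0)
        greedy = mm.MaintenanceModel(prefactor=1.0)
        assert mm.minimum_ch4_threshold(lr1, hot, greedy) == math.inf


class TestArealBudget:
    def test_sink_arithmetic(self):
        assert mm.net_ch4_sink(8.8e5, 2.2e5) == pytest.approx(6.6e5, rel=1e-14)
        assert mm.net_ch4_sink(10.0, 10.0) == 0.0
        assert mm.net_ch4_sink(10.0, 3.0) == 7.0
        with pytest.raises(mm.ThermodynamicDomainError):
            mm.net_ch4_sink(1.0, 2.0)

    def test_density_linear_in_flux(self, lr1, mars_atm):
        d1 = mm.areal_cell_density(lr1, mars_atm, 6.6e5)
        d2 = mm.areal_cell_density(lr1, mars_atm, 2 * 6.6e5)
        assert d2 == pytest.approx(2 * d1, rel=1e-14)
        assert mm.areal_cell_density(lr1, mars_atm, 0.0) == 0.0

    def test_density_chained_arithmetic(self, lr1, mars_atm):
        r = mm.oxidation_rate_at(lr1, mars_atm)
        expected = 6.6e5 / 6.02214076e23 * 3600.0 / r
        assert mm.areal_cell_density(lr1, mars_atm, 6.6e5) == pytest.approx(
            expected, rel=1e-12
        )

    def test_published_convention_omits_3600(self, lr1, mars_atm):
        d_h = mm.areal_cell_density(lr1, mars_atm, 6.6e5, per_hour=True)
        d_s = mm.areal_cell_density(lr1, mars_atm, 6.6e5, per_hour=False)
        assert d_h == pytest.approx(3600.0 * d_s, rel=1e-12)

    def test_biomass_conversion(self):
        assert mm.areal_biomass(1.6e6, 12.0) == pytest.approx(1.9e-4, rel=0.02)
        assert mm.areal_biomass(0.0, 12.0) == 0.0
        assert mm.areal_biomass(1.0, 1.0) == pytest.approx(1e-11, rel=1e-14, abs=0)


class TestMaintenanceUnits:
    def test_nitrifier_definition(self):
        obs = mm.MaintenanceObservation(
            T=260.0, value=1.0, source_units="gC_per_gC_h", organism_class="nitrifier"
        )
        assert mm.convert_maintenance_units(obs) == pytest.approx(291.4 * 12.01, rel=1e-12)

    def test_energy_units_pass_through(self):
        obs = mm.MaintenanceObservation(T=260.0, value=3.5)
        assert mm.convert_maintenance_units(obs) == 3.5

    def test_heterotroph_uses_supplied_synthesis_energy(self):
        # methanol: C=1, γ=6
        per_gc = synthesis_energy_per_gC(1, 6.0)
        obs = mm.MaintenanceObservation(
            T=260.0, value=2.0, source_units="gC_per_gC_h", organism_class="heterotroph"
        )
        got = mm.convert_maintenance_units(obs, biomass_energy_per_gC=per_gc)
        assert got == pytest.approx(2.0 * per_gc * 12.01, rel=1e-12)

    def test_heterotroph_without_energy_rejected(self):
        obs = mm.MaintenanceObservation(
            T=260.0, value=2.0, source_units="gC_per_gC_h", organism_class="heterotroph"
        )
        with pytest.raises(mm.ConfigurationError):
            mm.convert_maintenance_units(obs)


class TestArrheniusFit:
    def test_noise_free_recovery(self, maintenance):
        temps = [233.0, 243.0, 253.0, 263.0, 273.0]
        obs = mm.synth_maintenance_dataset(maintenance, temps, noise_sigma=0.0)
        res = mm.fit_arrhenius_maintenance(obs)
        assert res.arrh_A == pytest.approx(144.9, rel=1e-6)
        assert res.arrh_B == pytest.approx(39656.0, rel=1e-6)
        model = res.maintenance_model()
        assert model.rate(230.0) == pytest.approx(
            mm.maintenance_rate(maintenance, 230.0), rel=1e-6
        )

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(mm.FitError):
            MaintenanceArrheniusModel([250.0], [1e-12])
        with pytest.raises(mm.FitError):
            # warm observations are excluded before fitting
            MaintenanceArrheniusModel([300.0, 305.0, 310.0], [1.0, 2.0, 3.0])

    def test_confidence_band_contains_fitted_line(self, maintenance):
        temps = list(np.linspace(233.0, 281.0, 30))
        obs = mm.synth_maintenance_dataset(maintenance, temps, noise_sigma=0.5, seed=7)
        res = mm.fit_arrhenius_maintenance(obs)
        grid = np.linspace(235.0, 280.0, 10)
        lo, hi = res.confidence_band(grid)
        mid = res.predict(grid)
        assert np.all(lo < mid) and np.all(mid < hi)

    def test_summary_mentions_parameters(self, maintenance):
        obs = mm.synth_maintenance_dataset(maintenance, [233.0, 253.0, 273.0])
        res = mm.fit_arrhenius_maintenance(obs)
        text = res.summary()
        assert "A =" in text and "B =" in text
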