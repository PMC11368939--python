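"""Equation-of-state consistency: exact limits, finite-difference oracles,
a grid-scan golden density, and the deviation metric."""

import numpy as np
import pytest

import aminochol as ac
from aminochol.epcsaft.constants import ETA_MAX, K_B
from aminochol.epcsaft.eos import EpcSaft
from aminochol.epcsaft.params import ParamSet, PureParams
from aminochol.errors import ConfigurationError, DomainError, NoSolutionError


@pytest.fixture(scope="module")
def water_x():
    return {"water": 1.0}


class TestWaterDiameter:
    def test_room_temperature_value(self):
        # direct evaluation of the exponential correlation
        assert ac.water_segment_diameter(298.15) == pytest.approx(2.797, abs=2e-3)

    def test_high_temperature_limit(self):
        with pytest.warns(UserWarning):
            assert ac.water_segment_diameter(5000.0) == pytest.approx(2.7927, abs=1e-6)

    def test_temperature_dependence_is_material(self):
        assert ac.water_segment_diameter(288.15) != ac.water_segment_diameter(318.15)


class TestComposition:
    def test_pure_water(self):
        assert ac.mixture_from_molality(0.0, 0.0) == {"water": 1.0}

    def test_ternary_arithmetic(self):
        x = ac.mixture_from_molality(0.1, 0.05, "l-glycine")
        total = 1000.0 / 18.0153 + 0.05 + 0.2
        assert x["water"] == pytest.approx((1000.0 / 18.0153) / total, rel=1e-10)
        assert x["choline"] == pytest.approx(0.1 / total, rel=1e-10)
        assert x["choline"] == pytest.approx(1.793e-3, rel=1e-3)

    def test_sums_to_one_and_electroneutral(self):
        x = ac.mixture_from_molality(0.3, 0.15, "l-proline")
        assert sum(x.values()) == pytest.approx(1.0, rel=1e-14)
        assert x["choline"] == x["chloride"]

    def test_molecular_salt_option(self):
        x = ac.mixture_from_molality(0.1, 0.0, dissociate=False)
        assert "choline chloride" in x and "choline" not in x

    def test_negative_molality_rejected(self):
        with pytest.raises(DomainError):
            ac.mixture_from_molality(-0.1, 0.0)


class TestHelmholtzLimits:
    def test_zero_density_all_contributions_vanish(self, exp_eos, water_x):
        bd = exp_eos.helmholtz(298.15, 0.0, water_x)
        assert (bd.a_hc, bd.a_disp, bd.a_assoc, bd.a_ion) == (0.0, 0.0, 0.0, 0.0)

    def test_association_off_means_zero_term_and_unit_sites(self):
        p = ParamSet([PureParams("sphere", 1.0, 3.0, 200.0, molar_mass=40.0)])
        bd = EpcSaft(p).helmholtz(300.0, 0.01, {"sphere": 1.0})
        assert bd.a_assoc == 0.0 and bd.site_fractions == {}

    def test_site_fractions_in_unit_interval(self, exp_eos):
        x = ac.mixture_from_molality(0.2, 0.1, "l-glycine")
        bd = exp_eos.helmholtz(298.15, 0.03, x)
        for xa, xb in bd.site_fractions.values():
            assert 0.0 < xa <= 1.0 and 0.0 < xb <= 1.0

    def test_mass_action_residual_at_convergence(self, exp_eos):
        x = ac.mixture_from_molality(0.2, 0.1, "l-glycine")
        names, xv = exp_eos._split(x)
        p = exp_eos._prepare(298.15, names)
        rho = 0.032
        (XA, XB, idx, D), _ = exp_eos._solve_sites(p, xv, rho)
        xa = xv[idx]
        resA = XA - 1.0 / (1.0 + rho * D @ (xa * p.n_don[idx] * XB))
        resB = XB - 1.0 / (1.0 + rho * D.T @ (xa * p.n_acc[idx] * XA))
        assert np.max(np.abs(resA)) < 1e-11 and np.max(np.abs(resB)) < 1e-11

    def test_no_ions_means_zero_ion_term(self, exp_eos):
        x = ac.mixture_from_molality(0.0, 0.1, "l-glycine")
        bd = exp_eos.helmholtz(298.15, 0.03, x)
        assert bd.a_ion == 0.0

    def test_ion_term_negative_and_dilute_scaling(self, exp_eos):
        # a_ion < 0 and ~ (ionic strength)^(3/2) in the dilute limit
        a = []
        for scale in (1.0, 4.0):
            x = ac.mixture_from_molality(1e-4 * scale, 0.0)
            p = exp_eos._prepare(298.15, tuple(x))
            xv = np.array([x[k] for k in x])
            a.append(exp_eos._a_ion(p, xv, 0.0333, 298.15))
        assert a[0] < 0 and a[1] < 0
        # molality x4 at near-constant total moles -> a_ion x8
        assert a[1] / a[0] == pytest.approx(8.0, rel=0.05)

    def test_packing_fraction_cap(self, exp_eos, water_x):
        with pytest.raises(Exception, match="packing"):
            exp_eos.helmholtz(298.15, 1.0, water_x)


class TestCompressibility:
    def test_ideal_gas_limit(self, exp_eos, water_x):
        Z, P = exp_eos.compressibility_and_pressure(298.15, 1e-12, water_x)
        assert Z == pytest.approx(1.0, abs=1e-6)
        assert P == pytest.approx(1e-12 * 1e30 * K_B * 298.15, rel=1e-6)

    def test_hard_sphere_virial_limit(self):
        # pure m=1 hard sphere: Z ~ 1 + 4 eta at low packing
        p = ParamSet([PureParams("hs", 1.0, 3.0, 1e-12, molar_mass=40.0)])
        eos = EpcSaft(p)
        x = {"hs": 1.0}
        fac = eos.packing_fraction(300.0, 1.0, x)
        for eta in (1e-4, 1e-3):
            Z, _ = eos.compressibility_and_pressure(300.0, eta / fac, x)
            assert Z - 1.0 == pytest.approx(4.0 * eta, rel=0.02)

    def test_analytic_matches_finite_difference(self, exp_eos):
        rng = np.random.default_rng(20)
        for _ in range(6):
            T = rng.uniform(285.0, 320.0)
            rho = rng.uniform(0.005, 0.033)
            x = ac.mixture_from_molality(
                rng.uniform(0.0, 0.3), rng.uniform(0.0, 0.15), "l-glycine"
            )
            Z, _ = exp_eos.compressibility_and_pressure(T, rho, x)
            h = rho * 1e-5
            ap = exp_eos.helmholtz(T, rho + h, x).total
            am = exp_eos.helmholtz(T, rho - h, x).total
            Z_fd = 1.0 + rho * (ap - am) / (2.0 * h)
            assert Z == pytest.approx(Z_fd, rel=1e-6)


class TestDensitySolver:
    def test_pure_water_golden_value(self, exp_eos, water_x):
        """Liquid root frozen against an independent fine-grid scan of
        P(eta) (10^4 points + bisection), run once while pinning this test."""
        res = ac.solve_density(exp_eos, 298.15, 87150.0, water_x)
        assert res.root_type == "liquid"
        assert 950.0 < res.mass_density < 1050.0
        assert res.mass_density == pytest.approx(997.0028, abs=0.01)

    def test_ideal_gas_parameter_limit(self):
        p = ParamSet([PureParams("ideal", 1.0, 0.5, 1e-12, molar_mass=40.0)])
        res = ac.solve_density(EpcSaft(p), 300.0, 1e5, {"ideal": 1.0})
        rho_ideal = 1e5 / (K_B * 300.0) / 1e30
        assert res.number_density == pytest.approx(rho_ideal, rel=1e-3)

    def test_fixed_point_residual(self, exp_eos):
        x = ac.mixture_from_molality(0.2, 0.1, "l-glycine")
        res = ac.solve_density(exp_eos, 298.15, 87150.0, x)
        _, P = exp_eos.compressibility_and_pressure(
            298.15, res.number_density, x
        )
        assert abs(P - 87150.0) / 87150.0 < 1e-8

    def test_warm_start_matches_cold_start(self, exp_eos, water_x):
        cold = ac.solve_density(exp_eos, 298.15, 87150.0, water_x)
        warm = ac.solve_density(
            exp_eos, 298.15, 87150.0, water_x, eta_guess=cold.packing_fraction
        )
        assert warm.mass_density == pytest.approx(cold.mass_density, rel=1e-10)
        assert warm.iterations < cold.iterations

    def test_no_root_raises(self, exp_eos, water_x):
        with pytest.raises(NoSolutionError):
            ac.solve_density(exp_eos, 298.15, -1.0, water_x)


class TestPredictionDriver:
    def test_missing_species_is_configuration_error(self, bundled_table):
        p = ParamSet([PureParams("water", 1.2, 2.8, 350.0, molar_mass=18.0153)])
        with pytest.raises(ConfigurationError, match="lacks species"):
            ac.predict_density_table(bundled_table, EpcSaft(p))

    def test_single_record_deterministic(self, exp_eos):
        recs = [
            ac.MeasurementRecord(ac.SystemKey("l-glycine", 0.05), 298.15, 0.0, 998.63, 1499.29),
        ]
        t = ac.MeasurementTable(recs)
        a = ac.predict_density_table(t, exp_eos)
        b = ac.predict_density_table(t, exp_eos)
        assert a[0] == b[0]
        # baseline row is a binary water + amino acid prediction
        assert a[0] == pytest.approx(998.63, rel=0.02)


class TestArdPercent:
    def test_identity_is_zero(self):
        assert ac.ard_percent([1000.0, 1010.0], [1000.0, 1010.0]) == 0.0

    def test_hand_arithmetic(self):
        assert ac.ard_percent([1000.0, 1010.0], [990.0, 1010.0]) == pytest.approx(0.5)
        assert ac.ard_percent([1000.0], [1100.0]) == pytest.approx(10.0)

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            ac.ard_percent([1000.0], [990.0, 1010.0])


class TestParamLoading:
    def test_bundled_sets_well_formed(self):
        for source in ("experimental", "cosmo", "cosmo_alt"):
            ps = ac.load_bundled_params(source)
            assert "water" in ps and "l-glycine" in ps
        assert ac.load_bundled_params("experimental").has_ions
        assert not ac.load_bundled_params("cosmo").has_ions

    def test_unknown_source(self):
        with pytest.raises(ConfigurationError):
            ac.load_bundled_params("mystery")

    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            PureParams("bad", 1.0, 3.0, 200.0, "2B", 2000.0, 1.5, 0, 10.0)
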