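"""Redlich-Mayer fitting, the temperature polynomial and the Hepler criterion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aminochol as ac
from aminochol.errors import DomainError, FitError
from aminochol.redlich_mayer import StructureClass


class TestRedlichMayerFit:
    def test_noise_free_recovery_to_machine_precision(self):
        m = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
        y = 100.0 + 5.0 * np.sqrt(m) - 2.0 * m
        fit = ac.fit_redlich_mayer(list(zip(m, y)))
        assert fit.intercept == pytest.approx(100.0, abs=1e-9)
        assert fit.s_coeff == pytest.approx(5.0, abs=1e-8)
        assert fit.b_coeff == pytest.approx(-2.0, abs=1e-8)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_saturated_three_point_fit_interpolates(self):
        m = np.array([0.1, 0.2, 0.3])
        y = 50.0 - 3.0 * np.sqrt(m) + 1.5 * m
        fit = ac.fit_redlich_mayer(list(zip(m, y)))
        assert fit.residual_sd == 0.0
        assert fit.predict(m) == pytest.approx(y, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            ac.fit_redlich_mayer([(0.1, 1.0), (0.2, 2.0)])

    def test_duplicate_molalities_rejected(self):
        with pytest.raises(FitError, match="[Dd]uplicate"):
            ac.fit_redlich_mayer([(0.1, 1.0), (0.1, 1.1), (0.2, 2.0), (0.3, 2.5)])

    def test_nonpositive_molalities_rejected(self):
        with pytest.raises(DomainError):
            ac.fit_redlich_mayer([(0.0, 1.0), (0.1, 1.1), (0.2, 2.0)])

    def test_glycine_block_reproduces_printed_intercept(self, property_records):
        pts = [
            (r.m_chcl, r.v_phi * 1e6)
            for r in property_records
            if r.system.amino_acid == "l-glycine"
            and abs(r.system.amino_acid_molality - 0.05) < 1e-9
            and r.T == 288.15
        ]
        assert len(pts) == 6
        fit = ac.fit_redlich_mayer(pts)
        assert fit.intercept == pytest.approx(121.97, abs=0.1)

    def test_fitted_curve_stays_within_two_residual_sd(self, property_records):
        by_group = {}
        for r in property_records:
            by_group.setdefault((r.system, r.T), []).append(r)
        for recs in by_group.values():
            pts = np.array([(r.m_chcl, r.v_phi * 1e6) for r in recs])
            fit = ac.fit_redlich_mayer(pts)
            resid = np.abs(pts[:, 1] - fit.predict(pts[:, 0]))
            assert np.all(resid <= 2.0 * max(fit.residual_sd, 1e-12))


class TestTemperaturePolynomial:
    def test_exact_parabola_recovered(self):
        T = np.array([288.15, 298.15, 308.15, 318.15])
        y = 1.0 + 0.1 * T + 0.001 * T * T
        fit = ac.fit_vphi0_temperature(list(zip(T, y)))
        assert fit.a0 == pytest.approx(1.0, abs=1e-6)
        assert fit.b1 == pytest.approx(0.1, rel=1e-9)
        assert fit.c2 == pytest.approx(0.001, rel=1e-10)

    def test_exact_line_gives_zero_curvature(self):
        T = np.array([288.15, 298.15, 308.15, 318.15])
        fit = ac.fit_vphi0_temperature(list(zip(T, 10.0 + 0.05 * T)))
        assert fit.c2 == pytest.approx(0.0, abs=1e-12)
        summary = ac.hepler_analysis(fit)
        assert summary.structure_class is StructureClass.INDETERMINATE

    def test_too_few_temperatures(self):
        with pytest.raises(FitError):
            ac.fit_vphi0_temperature([(288.15, 1.0), (298.15, 2.0)])


class TestDerivedQuantities:
    def test_expansibility_constant_when_curvature_zero(self):
        T = [280.0, 300.0, 320.0]
        fit = ac.fit_vphi0_temperature([(t, 100.0 + 0.07 * t) for t in T])
        e, a = ac.expansibility_and_alpha(fit)
        assert all(v == pytest.approx(0.07, rel=1e-9) for v in e.values())

    def test_alpha_division_oracle(self):
        # V0 = 100, E0 = 0.07 (1e6 scale) -> alpha = 7.0e-4 K^-1
        fit = ac.fit_vphi0_temperature(
            [(280.0, 100.0 - 0.07 * 20), (300.0, 100.0), (320.0, 100.0 + 0.07 * 20)]
        )
        _, a = ac.expansibility_and_alpha(fit, [300.0])
        assert a[300.0] == pytest.approx(7.0e-4, rel=1e-6)

    def test_dcp_dp_arithmetic(self):
        # parabola with C = -0.005 -> dCp/dP at 300 K = -2CT = +3.0
        Ts = [280.0, 300.0, 320.0]
        fit = ac.fit_vphi0_temperature([(t, 1.0 + 0.0 * t - 0.005 * t * t) for t in Ts])
        summary = ac.hepler_analysis(fit)
        assert summary.hepler_d2 == pytest.approx(-0.01, rel=1e-9)
        assert summary.dcp_dp[300.0] == pytest.approx(3.0, rel=1e-9)
        assert summary.structure_class is StructureClass.BREAKER

    @given(c=st.floats(-1e-5, 1e-5), b=st.floats(-0.1, 0.1))
    def test_dcp_dp_over_curvature_is_minus_T(self, c, b):
        Ts = [280.0, 300.0, 320.0]
        fit = ac.fit_vphi0_temperature([(t, 100.0 + b * t + c * t * t) for t in Ts])
        summary = ac.hepler_analysis(fit, indeterminate_threshold=0.0)
        if summary.hepler_d2 != 0.0:
            for T in Ts:
                assert summary.dcp_dp[T] / summary.hepler_d2 == pytest.approx(-T, rel=1e-6)


class TestFullSystemDriver:
    def test_one_row_per_system_temperature(self, property_records):
        frame = ac.fits_to_frame(ac.fit_system_groups(property_records))
        assert len(frame) == 36
        # the low-concentration glycine system carries the canonical numbers
        g = frame[(frame.amino_acid == "l-glycine") & (frame.m_aa_molal == 0.05)]
        assert g[g.T_K == 288.15].v_phi0_1e6.iloc[0] == pytest.approx(121.97, abs=0.1)
        assert (g.structure_class == "maker").all()
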