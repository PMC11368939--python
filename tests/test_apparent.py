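"""Apparent molar properties: arithmetic oracles, printed-value checks,
and algebraic invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import aminochol as ac
from aminochol.apparent import TasteFlag
from aminochol.errors import DomainError
from conftest import record


class TestIsentropicCompressibility:
    def test_unit_inputs(self):
        assert ac.isentropic_compressibility(1.0, 1.0) == 1.0

    def test_direct_arithmetic(self):
        # 1 / (998.2 * 1482.3^2)
        assert ac.isentropic_compressibility(998.2, 1482.3) == pytest.approx(
            4.5594e-10, rel=1e-4
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            ac.isentropic_compressibility(-1.0, 1482.3)

    @given(
        d=st.floats(900.0, 1100.0),
        u1=st.floats(1400.0, 1500.0),
        du=st.floats(0.1, 100.0),
    )
    def test_decreases_with_speed_at_fixed_density(self, d, u1, du):
        assert ac.isentropic_compressibility(d, u1 + du) < ac.isentropic_compressibility(d, u1)


class TestApparentMolarVolume:
    def test_density_match_limit_is_M_over_d(self):
        assert ac.apparent_molar_volume(0.1, 1000.0, 1000.0, 0.1) == pytest.approx(
            0.1 / 1000.0, rel=1e-14
        )

    def test_direct_arithmetic(self):
        # M/d - (d-d0)/(m d d0) with m=0.1, d=1050, d0=1000, M=0.100
        expect = 0.100 / 1050.0 - 50.0 / (0.1 * 1050.0 * 1000.0)
        got = ac.apparent_molar_volume(0.1, 1050.0, 1000.0, 0.100)
        assert got == pytest.approx(expect, rel=1e-14)
        assert got == pytest.approx(-3.8095e-4, rel=1e-4)

    def test_undefined_at_baseline(self):
        with pytest.raises(DomainError, match="baseline"):
            ac.apparent_molar_volume(0.0, 1000.0, 1000.0, 0.1)


class TestApparentMolarCompressibility:
    def test_solvent_match_limit(self):
        ks = 4.5e-10
        got = ac.apparent_molar_isentropic_compressibility(
            0.1, 1000.0, 1000.0, ks, ks, 0.1
        )
        assert got == pytest.approx(ks * 0.1 / 1000.0, rel=1e-14)

    def test_direct_arithmetic(self):
        got = ac.apparent_molar_isentropic_compressibility(
            0.1, 1000.0, 1000.0, 4.0e-10, 4.5e-10, 0.1
        )
        assert got == pytest.approx(-4.6e-13, rel=1e-10)


class TestTasteDescriptors:
    def test_constructed_midpoint_is_ideal(self):
        M = 0.13962
        asv, _, flag = ac.taste_descriptors(0.6e-3 * M, 0.0, M)
        assert asv * 1e3 == pytest.approx(0.600)
        assert flag is TasteFlag.IDEAL_SWEETNESS

    def test_division_oracle_asic(self):
        _, asic, _ = ac.taste_descriptors(0.0, -1.913e-14, 0.13962)
        assert asic == pytest.approx(-1.370e-13, rel=1e-3)

    @given(
        v_phi=st.floats(-1e-3, 1e-3),
        kappa_phi=st.floats(-1e-12, 1e-12),
        M=st.floats(0.01, 1.0),
    )
    def test_asv_and_asic_invert_exactly(self, v_phi, kappa_phi, M):
        asv, asic, _ = ac.taste_descriptors(v_phi, kappa_phi, M)
        assert asv * M == pytest.approx(v_phi, rel=1e-12, abs=1e-18)
        assert asic * M == pytest.approx(kappa_phi, rel=1e-12, abs=1e-24)


class TestBundledChain:
    """Recomputed properties versus the printed reference tabulation."""

    def test_record_count(self, property_records):
        assert len(property_records) == 216  # 252 rows - 36 baselines

    def test_single_group_two_row_table(self):
        recs = [
            ac.MeasurementRecord(ac.SystemKey("l-glycine", 0.05), 298.15, 0.0, 998.2, 1482.3),
            ac.MeasurementRecord(ac.SystemKey("l-glycine", 0.05), 298.15, 0.1, 999.9, 1486.0),
        ]
        out = ac.build_property_table(ac.MeasurementTable(recs))
        assert len(out) == 1

    @pytest.mark.parametrize(
        "aa,m_aa,T,m_chcl,v_phi_1e6",
        [
            ("l-glycine", 0.05, 288.15, 0.0499, 122.41),
            ("l-glycine", 0.15, 318.15, 0.2993, 126.91),
            ("l-glycine", 0.05, 318.15, 0.0499, 124.93),
            ("d,l-alanine", 0.0999, 298.15, 0.2503, 123.83),
            ("l-proline", 0.1488, 298.15, 0.2955, 123.72),
        ],
    )
    def test_v_phi_matches_printed_table(self, property_records, aa, m_aa, T, m_chcl, v_phi_1e6):
        r = record(property_records, aa, m_aa, T, m_chcl)
        assert r.v_phi * 1e6 == pytest.approx(v_phi_1e6, abs=0.1)

    def test_kappa_phi_first_glycine_point(self, property_records):
        r = record(property_records, "l-glycine", 0.05, 288.15, 0.0499)
        assert r.kappa_phi * 1e14 == pytest.approx(-1.91, abs=0.05)

    def test_every_bundled_asv_is_above_ideal_band(self, property_records):
        # the study's central sensory conclusion: ASV ~ 0.88 >> 0.7 everywhere
        assert all(r.taste_flag is TasteFlag.ABOVE_IDEAL for r in property_records)
        assert all(0.85 < r.asv * 1e3 < 0.92 for r in property_records)
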