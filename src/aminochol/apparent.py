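"""Apparent molar properties and empirical taste descriptors.

For a solution of choline chloride (molar mass ``M``, molality ``m``) in an
amino-acid/water solvent of density ``d0``, the solute's effective per-mole
contributions are

    kappa_S = 1 / (d u^2)                       (Newton-Laplace)
    V_phi   = M/d - (d - d0) / (m d d0)
    kappa_phi = (kappa_S d0 - d kappa_S0) / (m d d0) + kappa_S M / d

with all quantities in SI.  ``kappa_S``/``kappa_S0`` always enter at full
floating-point precision from the Newton-Laplace relation; the rounded
3-figure compressibilities a report would print are far too coarse for
``kappa_phi`` (using them shifts the first glycine point from -1.91e-14 to
-2.41e-14 m^3 mol^-1 Pa^-1).

The apparent specific volume ASV = V_phi / M (cm^3 g^-1) is an empirical
sweetness descriptor; solutes in the band 0.5 < ASV < 0.7 cm^3 g^-1 taste
ideally sweet.  ASIC = kappa_phi / M plays the analogous role for
saltiness.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .data import M_CHCL_KG_MOL, MeasurementTable, SystemKey
from .errors import DomainError

#: Multiplier taking an SI quantity to the customary reporting scale.
REPORT_SCALES = {
    "kappa_s": 1e10,  # Pa^-1 -> 10^10 Pa^-1
    "v_phi": 1e6,  # m^3/mol -> 10^6 m^3/mol
    "kappa_phi": 1e14,  # m^3/(mol Pa) -> 10^14
    "asv": 1e3,  # m^3/kg -> cm^3/g
    "asic": 1e11,  # m^3/(kg Pa) -> 10^11
}

ASV_IDEAL_SWEETNESS = (0.5, 0.7)  # cm^3 g^-1


class TasteFlag(str, enum.Enum):
    BELOW_IDEAL = "below_ideal"
    IDEAL_SWEETNESS = "ideal_sweetness"
    ABOVE_IDEAL = "above_ideal"


def isentropic_compressibility(d: float, u: float) -> float:
    """kappa_S = 1/(d u^2) in Pa^-1 for d in kg m^-3 and u in m s^-1."""
    if d <= 0 or u <= 0:
        raise DomainError("density and speed of sound must be positive")
    return 1.0 / (d * u * u)


def apparent_molar_volume(m: float, d: float, d0: float, M: float = M_CHCL_KG_MOL) -> float:
    """V_phi in m^3 mol^-1; ``m`` in mol kg^-1, densities in kg m^-3, M in kg mol^-1."""
    if d <= 0 or d0 <= 0 or M <= 0:
        raise DomainError("densities and molar mass must be positive")
    if m <= 0:
        raise DomainError("apparent molar volume is undefined at the solvent baseline (m = 0)")
    return M / d - (d - d0) / (m * d * d0)


def apparent_molar_isentropic_compressibility(
    m: float,
    d: float,
    d0: float,
    ks: float,
    ks0: float,
    M: float = M_CHCL_KG_MOL,
) -> float:
    """kappa_phi in m^3 mol^-1 Pa^-1 from full-precision compressibilities."""
    if min(d, d0, ks, ks0, M) <= 0:
        raise DomainError("densities, compressibilities and molar mass must be positive")
    if m <= 0:
        raise DomainError(
            "apparent molar compressibility is undefined at the solvent baseline (m = 0)"
        )
    return (ks * d0 - d * ks0) / (m * d * d0) + ks * M / d


def taste_descriptors(
    v_phi: float, kappa_phi: float, M: float = M_CHCL_KG_MOL
) -> tuple[float, float, TasteFlag]:
    """(ASV, ASIC, flag) in SI (m^3 kg^-1, m^3 kg^-1 Pa^-1).

    The sweetness classification applies the 0.5-0.7 band with ASV
    expressed in cm^3 g^-1 (the customary reporting scale).
    """
    if M <= 0:
        raise DomainError("molar mass must be positive")
    asv = v_phi / M
    asic = kappa_phi / M
    asv_cm3_g = asv * REPORT_SCALES["asv"]
    lo, hi = ASV_IDEAL_SWEETNESS
    if asv_cm3_g <= lo:
        flag = TasteFlag.BELOW_IDEAL
    elif asv_cm3_g < hi:
        flag = TasteFlag.IDEAL_SWEETNESS
    else:
        flag = TasteFlag.ABOVE_IDEAL
    return asv, asic, flag


@dataclass(frozen=True)
class ApparentPropertyRecord:
    """Derived properties of one non-baseline state point (SI units)."""

    system: SystemKey
    T: float
    m_chcl: float
    kappa_s: float
    kappa_s0: float
    v_phi: float
    kappa_phi: float
    asv: float
    asic: float
    taste_flag: TasteFlag


def build_property_table(
    table: MeasurementTable, M: float = M_CHCL_KG_MOL
) -> list[ApparentPropertyRecord]:
    """One derived record per non-baseline row, deterministic ordering.

    The solvent baseline of each record is the m_chcl = 0 row of the same
    amino-acid system at the same temperature.
    """
    out: list[ApparentPropertyRecord] = []
    for (system, T), recs in sorted(table.groups().items()):
        base = next(r for r in recs if r.m_chcl == 0.0)
        ks0 = isentropic_compressibility(base.d, base.u)
        for r in recs:
            if r.m_chcl == 0.0:
                continue
            ks = isentropic_compressibility(r.d, r.u)
            v_phi = apparent_molar_volume(r.m_chcl, r.d, base.d, M)
            kappa_phi = apparent_molar_isentropic_compressibility(
                r.m_chcl, r.d, base.d, ks, ks0, M
            )
            asv, asic, flag = taste_descriptors(v_phi, kappa_phi, M)
            out.append(
                ApparentPropertyRecord(
                    system=system,
                    T=T,
                    m_chcl=r.m_chcl,
                    kappa_s=ks,
                    kappa_s0=ks0,
                    v_phi=v_phi,
                    kappa_phi=kappa_phi,
                    asv=asv,
                    asic=asic,
                    taste_flag=flag,
                )
            )
    return out


def properties_to_frame(records: list[ApparentPropertyRecord], scaled: bool = True) -> pd.DataFrame:
    """Long-form DataFrame; ``scaled`` applies the customary reporting scales."""
    rows = []
    for r in records:
        row = {
            "amino_acid": r.system.amino_acid,
            "m_aa_molal": r.system.amino_acid_molality,
            "T_K": r.T,
            "m_chcl_molal": r.m_chcl,
            "kappa_s": r.kappa_s,
            "kappa_s0": r.kappa_s0,
            "v_phi": r.v_phi,
            "kappa_phi": r.kappa_phi,
            "asv": r.asv,
            "asic": r.asic,
            "taste_flag": r.taste_flag.value,
        }
        if scaled:
            for col, scale in REPORT_SCALES.items():
                row[col] = row[col] * scale
            row["kappa_s0"] = r.kappa_s0 * REPORT_SCALES["kappa_s"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if scaled:
        df = df.rename(
            columns={
                "kappa_s": "kappa_s_1e10_Pa",
                "kappa_s0": "kappa_s0_1e10_Pa",
                "v_phi": "v_phi_1e6_m3_mol",
                "kappa_phi": "kappa_phi_1e14_m3_mol_Pa",
                "asv": "asv_cm3_g",
                "asic": "asic_1e11_m3_kg_Pa",
            }
        )
    return df
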