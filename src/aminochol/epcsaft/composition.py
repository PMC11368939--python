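"""Molality -> mole-fraction conversion for the ternary solutions.

Compositions are built per kilogram of water (n_water = 1000/18.0153 mol).
Choline chloride is a strong electrolyte: by default it dissociates fully
into one choline cation and one chloride anion per formula unit, which is
the speciation the ionic Helmholtz term requires.  With
``dissociate=False`` (used with the quantum-chemistry-derived parameter
set, which treats the salt as one neutral component) it stays molecular.
"""

from __future__ import annotations

from ..data import DEFAULT_MOLAR_MASSES
from ..errors import DomainError

N_WATER_PER_KG = 1000.0 / DEFAULT_MOLAR_MASSES["water"]  # 55.5084 mol


def mixture_from_molality(
    m_chcl: float,
    m_aa: float,
    amino_acid: str = "l-glycine",
    dissociate: bool = True,
) -> dict[str, float]:
    """Mole fractions of every species for the given molalities.

    Returns a dict species -> x; always sums to 1 and, when ions are
    present, is electroneutral by construction.
    """
    if m_chcl < 0 or m_aa < 0:
        raise DomainError("molalities must be >= 0")
    moles = {"water": N_WATER_PER_KG}
    if m_aa > 0:
        moles[amino_acid] = m_aa
    if m_chcl > 0:
        if dissociate:
            moles["choline"] = m_chcl
            moles["chloride"] = m_chcl
        else:
            moles["choline chloride"] = m_chcl
    total = sum(moles.values())
    return {k: v / total for k, v in moles.items()}
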