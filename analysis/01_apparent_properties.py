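#!/usr/bin/env python
"""Apparent molar volumes and isentropic compressibilities of choline
chloride in aqueous amino-acid solvents, from the bundled measurement set.

Writes results/apparent_properties.csv (one row per non-baseline state
point, customary reporting scales) and prints the canonical glycine state
point as a sanity anchor.
"""

from pathlib import Path

import aminochol as ac

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = ac.load_bundled_table1()
records = ac.build_property_table(table)
frame = ac.properties_to_frame(records)
frame.to_csv(OUT / "apparent_properties.csv", index=False, float_format="%.6g")

first = next(
    r
    for r in records
    if r.system == ac.SystemKey("l-glycine", 0.05)
    and r.T == 288.15
    and abs(r.m_chcl - 0.0499) < 1e-9
)
print(f"{len(table)} measured state points -> {len(records)} derived records")
print("glycine 0.0500 mol/kg solvent, 288.15 K, m_ChCl = 0.0499 mol/kg:")
print(f"  10^10 kappa_S0 = {first.kappa_s0 * 1e10:.3f} Pa^-1")
print(f"  10^6  V_phi    = {first.v_phi * 1e6:.2f} m^3/mol")
print(f"  10^14 kappa_phi = {first.kappa_phi * 1e14:.2f} m^3/(mol Pa)")
# temperature trend: compare each state point at the lowest and highest T
by_state = {}
for r in records:
    by_state.setdefault((r.system, r.m_chcl), {})[r.T] = r.v_phi
grew = sum(1 for d in by_state.values() if d[318.15] > d[288.15])
print(
    f"V_phi increases from 288.15 K to 318.15 K in {grew}/{len(by_state)} "
    "(system, molality) series"
)
print(f"wrote {OUT / 'apparent_properties.csv'}")
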