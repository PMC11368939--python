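species,area_A2,volume_A3,solvation_energy_kcal_mol,n_homo,n_lumo,e_homo_ev,e_lumo_ev
l-glycine,106.9712,86.7222,-13.06,20,21,-5.70,-1.07
"d,l-alanine",123.0834,105.1876,-12.76,24,25,-5.72,-1.13
l-proline,144.7045,132.6716,-11.98,31,32,-5.41,-1.08
choline chloride,186.1378,174.8311,-56.03,38,39,-5.07,0.40
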