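species,m_seg,sigma_A,eps_k_K,scheme,eps_assoc_k_K,kappa_assoc,charge,molar_mass,sigma_formula
water,1.204659,,353.9449,2B,2425.7,0.04509,0,18.0153,water
l-glycine,4.8495,2.3270,216.96,2B,2598.1,0.0393,0,75.07,
"d,l-alanine",5.4647,2.5222,287.59,2B,3176.6,0.0819,0,89.09,
l-proline,6.9811,2.5481,289.72,2B,5527.8,0.0362,0,115.13,
choline,1.0,5.9216,220.4883,none,,,1,104.171,
chloride,1.0,3.0575,47.2878,none,,,-1,35.453,
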