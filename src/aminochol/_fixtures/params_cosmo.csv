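species,m_seg,sigma_A,eps_k_K,scheme,eps_assoc_k_K,kappa_assoc,charge,molar_mass,sigma_formula
water,1.204659,,353.9449,2B,2425.7,0.04509,0,18.0153,water
l-glycine,5.756,2.4327,324.0,2B,1260.0,0.024,0,75.07,
"d,l-alanine",5.96,2.5645,230.0,2B,590.0,0.023,0,89.09,
l-proline,6.088,2.7513,294.0,2B,730.0,0.020,0,115.13,
choline chloride,7.462,2.818,2796.0,2B,8190.0,0.021,0,139.62,
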