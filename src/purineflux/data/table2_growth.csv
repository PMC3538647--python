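# Growth parameters for C. glutamicum wild type and site-directed mutants:
# specific growth rate mu (1/h), biomass yield Y_x/s (g CDW per mmol
# glucose) and specific glucose uptake rate q_S (mmol per g CDW per h).
strain,mu,mu_sd,y_xs,y_xs_sd,q_s,q_s_sd
ATCC13032,0.443,0.004,0.095,0.004,4.67,0.09
Dpgi,0.376,0.001,0.090,0.002,4.18,0.02
purF_K348Q,0.440,0.008,0.091,0.001,4.82,0.06
DpurA,0.455,0.006,0.090,0.001,5.05,0.02
DguaB2,0.320,0.007,0.073,0.004,4.38,0.03
DpurA_DguaB2,0.317,0.006,0.075,0.001,4.24,0.01
DpurA_DguaB2_purF_Dpgi,0.146,0.003,0.076,0.003,1.92,0.02
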