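# Intracellular purine intermediate concentrations (umol per g CDW) for
# C. glutamicum wild type and site-directed mutants; mean +/- sd over four
# biological replicates.  flag: ok = quantified, b = below detection limit,
# nd = not determined.  phase 2 rows carry the second-biomass-phase values
# reported for the two single-deletion strains with transient pools.
strain,compound,phase,mean,sd,flag
ATCC13032,AMP,1,8.13,0.50,ok
ATCC13032,adenosine,1,0.10,0.01,ok
ATCC13032,adenine,1,2.63,0.25,ok
ATCC13032,GMP,1,2.63,0.16,ok
ATCC13032,guanosine,1,0.04,0.00,ok
ATCC13032,guanine,1,3.27,0.28,ok
ATCC13032,IMP,1,0.49,0.06,ok
ATCC13032,inosine,1,0.13,0.05,ok
ATCC13032,hypoxanthine,1,0.28,0.03,ok
ATCC13032,XMP,1,,,b
ATCC13032,xanthosine,1,,,b
ATCC13032,xanthine,1,0.12,0.01,ok
Dpgi,AMP,1,9.07,0.52,ok
Dpgi,adenosine,1,0.09,0.01,ok
Dpgi,adenine,1,3.04,0.11,ok
Dpgi,GMP,1,3.65,0.17,ok
Dpgi,guanosine,1,,,b
Dpgi,guanine,1,3.85,0.17,ok
Dpgi,IMP,1,0.42,0.03,ok
Dpgi,inosine,1,0.21,0.04,ok
Dpgi,hypoxanthine,1,0.29,0.03,ok
Dpgi,XMP,1,,,b
Dpgi,xanthosine,1,,,b
Dpgi,xanthine,1,0.22,0.01,ok
purF_K348Q,AMP,1,10.24,0.78,ok
purF_K348Q,adenosine,1,0.12,0.02,ok
purF_K348Q,adenine,1,3.36,0.30,ok
purF_K348Q,GMP,1,4.75,0.27,ok
purF_K348Q,guanosine,1,0.03,0.00,ok
purF_K348Q,guanine,1,5.08,0.61,ok
purF_K348Q,IMP,1,0.55,0.05,ok
purF_K348Q,inosine,1,0.38,0.12,ok
purF_K348Q,hypoxanthine,1,0.28,0.03,ok
purF_K348Q,XMP,1,,,b
purF_K348Q,xanthosine,1,,,b
purF_K348Q,xanthine,1,0.11,0.00,ok
DpurA,AMP,1,10.66,0.22,ok
DpurA,AMP,2,17.93,1.18,ok
DpurA,adenosine,1,0.13,0.01,ok
DpurA,adenine,1,3.04,0.38,ok
DpurA,adenine,2,5.58,0.26,ok
DpurA,GMP,1,9.47,0.12,ok
DpurA,GMP,2,21.10,2.03,ok
DpurA,guanosine,1,0.03,0.01,ok
DpurA,guanine,1,5.07,1.45,ok
DpurA,guanine,2,10.27,0.62,ok
DpurA,IMP,1,30.72,0.48,ok
DpurA,IMP,2,43.99,3.32,ok
DpurA,inosine,1,0.28,0.06,ok
DpurA,hypoxanthine,1,11.87,1.00,ok
DpurA,hypoxanthine,2,17.92,1.26,ok
DpurA,XMP,1,,,b
DpurA,xanthosine,1,,,b
DpurA,xanthine,1,0.17,0.00,ok
DguaB2,AMP,1,10.11,0.05,ok
DguaB2,AMP,2,27.79,2.03,ok
DguaB2,adenosine,1,0.21,0.01,ok
DguaB2,adenine,1,4.03,0.13,ok
DguaB2,adenine,2,8.32,0.53,ok
DguaB2,GMP,1,3.92,0.19,ok
DguaB2,GMP,2,2.33,0.24,ok
DguaB2,guanosine,1,0.06,0.01,ok
DguaB2,guanine,1,35.67,1.65,ok
DguaB2,guanine,2,9.38,0.64,ok
DguaB2,IMP,1,6.39,0.21,ok
DguaB2,IMP,2,37.16,3.48,ok
DguaB2,inosine,1,0.85,0.06,ok
DguaB2,hypoxanthine,1,3.55,0.04,ok
DguaB2,hypoxanthine,2,16.19,1.34,ok
DguaB2,XMP,1,,,nd
DguaB2,xanthosine,1,,,nd
DguaB2,xanthine,1,,,nd
DpurA_DguaB2,AMP,1,3.69,0.54,ok
DpurA_DguaB2,adenosine,1,0.05,0.00,ok
DpurA_DguaB2,adenine,1,,,b
DpurA_DguaB2,GMP,1,0.65,0.07,ok
DpurA_DguaB2,guanosine,1,0.10,0.01,ok
DpurA_DguaB2,guanine,1,,,b
DpurA_DguaB2,IMP,1,21.91,0.89,ok
DpurA_DguaB2,inosine,1,1.26,0.08,ok
DpurA_DguaB2,hypoxanthine,1,80.65,3.19,ok
DpurA_DguaB2,XMP,1,,,nd
DpurA_DguaB2,xanthosine,1,,,nd
DpurA_DguaB2,xanthine,1,,,nd
DpurA_DguaB2_purF_Dpgi,AMP,1,3.57,0.20,ok
DpurA_DguaB2_purF_Dpgi,adenosine,1,0.15,0.03,ok
DpurA_DguaB2_purF_Dpgi,adenine,1,,,b
DpurA_DguaB2_purF_Dpgi,GMP,1,0.51,0.03,ok
DpurA_DguaB2_purF_Dpgi,guanosine,1,0.23,0.02,ok
DpurA_DguaB2_purF_Dpgi,guanine,1,,,b
DpurA_DguaB2_purF_Dpgi,IMP,1,12.88,0.74,ok
DpurA_DguaB2_purF_Dpgi,inosine,1,2.53,0.19,ok
DpurA_DguaB2_purF_Dpgi,hypoxanthine,1,101.53,1.09,ok
DpurA_DguaB2_purF_Dpgi,XMP,1,,,nd
DpurA_DguaB2_purF_Dpgi,xanthosine,1,,,nd
DpurA_DguaB2_purF_Dpgi,xanthine,1,,,nd
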