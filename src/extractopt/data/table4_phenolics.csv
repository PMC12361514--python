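parameter,group,mean,sd,n,ci_lower,ci_upper
Kaempferol_mg_kg,RSM,8373.35,6.20,3,8366.33,8380.37
Kaempferol_mg_kg,ANN-GA,8656.31,2.41,3,8653.58,8659.04
GallicAcid_mg_kg,RSM,3131.69,15.33,3,3114.34,3149.04
GallicAcid_mg_kg,ANN-GA,4969.18,2.30,3,4966.58,4971.78
4HydroxybenzoicAcid_mg_kg,RSM,358.52,4.70,3,353.20,363.84
4HydroxybenzoicAcid_mg_kg,ANN-GA,1680.16,1.55,3,1678.41,1681.91
Naringenin_mg_kg,RSM,4164.32,5.73,3,4157.84,4170.80
Naringenin_mg_kg,ANN-GA,5364.56,3.77,3,5360.29,5368.83
Quercetin_mg_kg,RSM,7162.80,2.78,3,7159.65,7165.95
Quercetin_mg_kg,ANN-GA,10295.26,2.77,3,10292.13,10298.39
Luteolin_mg_kg,RSM,2165.30,7.38,3,2156.92,2173.68
Luteolin_mg_kg,ANN-GA,2091.35,2.29,3,2088.84,2093.86
Catechinhydrate_mg_kg,RSM,966.24,2.34,3,963.59,968.89
Catechinhydrate_mg_kg,ANN-GA,527.82,1.57,3,525.99,529.65
Myricetin_mg_kg,RSM,2649.96,2.48,3,2647.15,2652.77
Myricetin_mg_kg,ANN-GA,2935.96,2.68,3,2933.05,2938.87
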