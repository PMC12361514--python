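parameter,group,mean,sd,n,ci_lower,ci_upper
TPC_mg_GAE_g,RSM,148.880,1.571,3,147.102,150.658
TPC_mg_GAE_g,ANN-GA,209.467,3.590,3,205.405,213.529
TFC_mg_QE_g,RSM,198.667,2.028,3,196.372,200.962
TFC_mg_QE_g,ANN-GA,263.867,2.643,3,260.876,266.858
FRAP_mg_TE_g,RSM,135.600,2.035,3,133.297,137.903
FRAP_mg_TE_g,ANN-GA,152.890,1.237,3,151.490,154.290
DPPH_mg_TE_g,RSM,104.320,1.689,3,102.409,106.231
DPPH_mg_TE_g,ANN-GA,121.477,2.276,3,118.901,124.053
TAS_mmol_L,RSM,8.238,0.022,3,8.213,8.263
TAS_mmol_L,ANN-GA,8.623,0.013,3,8.608,8.638
TOS_umol_L,RSM,18.614,0.045,3,18.563,18.665
TOS_umol_L,ANN-GA,19.184,0.057,3,19.120,19.248
OSI,RSM,0.226,0.001,3,0.225,0.227
OSI,ANN-GA,0.222,0.001,3,0.221,0.223
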