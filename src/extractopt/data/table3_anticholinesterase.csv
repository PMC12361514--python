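parameter,group,mean,sd,n,ci_lower,ci_upper
AChE_IC50_ug_mL,Galantamine,7.710,0.281,3,7.392,8.028
AChE_IC50_ug_mL,RSM,72.417,1.626,3,70.577,74.257
AChE_IC50_ug_mL,ANN-GA,61.687,1.696,3,59.768,63.606
BChE_IC50_ug_mL,Galantamine,16.830,0.196,3,16.608,17.052
BChE_IC50_ug_mL,RSM,88.303,1.190,3,86.956,89.650
BChE_IC50_ug_mL,ANN-GA,81.397,1.238,3,79.996,82.798
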