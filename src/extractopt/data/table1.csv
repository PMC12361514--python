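temperature_C,time_h,ethanol_pct,mean,sd,n
45,5,0,6.703,0.017,3
45,10,0,7.088,0.055,3
45,15,0,6.006,0.040,3
45,5,50,6.721,0.027,3
45,10,50,7.124,0.031,3
45,15,50,5.959,0.043,3
45,5,100,6.652,0.033,3
45,10,100,7.110,0.064,3
45,15,100,6.017,0.043,3
55,5,0,7.748,0.034,3
55,10,0,8.570,0.024,3
55,15,0,6.856,0.021,3
55,5,50,7.757,0.043,3
55,10,50,8.539,0.029,3
55,15,50,6.852,0.039,3
55,5,100,7.765,0.028,3
55,10,100,8.561,0.029,3
55,15,100,6.847,0.012,3
65,5,0,5.759,0.030,3
65,10,0,6.153,0.029,3
65,15,0,4.756,0.028,3
65,5,50,5.744,0.018,3
65,10,50,6.164,0.024,3
65,15,50,4.745,0.033,3
65,5,100,5.734,0.022,3
65,10,100,6.158,0.021,3
65,15,100,4.750,0.026,3
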