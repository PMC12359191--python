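energy_MeV,mu_over_rho_cm2_g
0.010,5.329
0.015,1.673
0.020,0.8096
0.030,0.3756
0.040,0.2683
0.050,0.2269
0.060,0.2059
0.080,0.1837
0.100,0.1707
0.150,0.1505
0.200,0.1370
0.300,0.1186
0.400,0.1061
0.500,0.0969
0.600,0.0896
0.800,0.0786
1.000,0.0707
1.250,0.0632
1.500,0.0575
2.000,0.0494
3.000,0.0397
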