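energy_MeV,range_mm
0.0100,0.0025
0.0203,0.0088
0.0306,0.0182
0.1270,0.215
0.1340,0.23
0.1820,0.39
0.1880,0.41
0.2190,0.52
0.2250,0.54
0.3230,0.94
0.5830,2.2
0.7650,3.1
0.9340,4.0
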