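energy_MeV,range_mm
5.70,0.046
5.87,0.048
6.06,0.050
6.34,0.054
7.07,0.064
8.38,0.085
8.79,0.091
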