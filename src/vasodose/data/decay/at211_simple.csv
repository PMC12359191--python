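nuclide,class,energy_MeV,yield
At-211,alpha,5.87,0.418
At-211,alpha,7.45,0.582
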