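name,z,D_um2_per_ms,c_baseline_mM
Na,1,1.33,150
K,1,1.96,3
X,-1,2.03,155.8
Ca,2,0.71,1.4
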