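# 19-channel cap: electrode names, one per line
Fp1
Fp2
F7
F3
Fz
F4
F8
T7
C3
Cz
C4
T8
P7
P3
Pz
P4
P8
O1
O2
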