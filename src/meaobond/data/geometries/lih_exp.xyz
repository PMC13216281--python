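2
LiH experimental r=1.5949 (NIST CCCBDB)
Li 0.000000 0.000000 0.000000
H 0.000000 0.000000 1.594900
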