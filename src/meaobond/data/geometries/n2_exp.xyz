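2
N2 experimental r=1.0977 (NIST CCCBDB)
N 0.000000 0.000000 0.000000
N 0.000000 0.000000 1.097700
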