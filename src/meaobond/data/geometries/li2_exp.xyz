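2
Li2 experimental r=2.6729 (NIST CCCBDB)
Li 0.000000 0.000000 0.000000
Li 0.000000 0.000000 2.672900
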