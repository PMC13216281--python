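3
Li3+ equilateral r=2.9916 optimized CCSD/6-311++G(d,p)
Li -1.495808 0.000000 0.000000
Li 1.495808 0.000000 0.000000
Li 0.000000 2.590816 0.000000
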