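7
C2H5+ optimized B3LYP/6-311++G(d,p) (bridged)
C -0.000056 -0.690159 0.008605
C -0.000057 0.690276 0.008501
H -0.000094 -0.000151 1.136723
H 0.934656 -1.246350 -0.001673
H -0.934550 -1.246712 -0.001596
H 0.934670 1.246450 -0.001620
H -0.934565 1.246819 -0.001575
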