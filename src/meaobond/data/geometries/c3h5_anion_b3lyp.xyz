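8
C3H5- optimized B3LYP/6-311++G(d,p)
C 0.000000 0.000000 0.345927
C -1.274556 0.000000 -0.219017
C 1.274556 -0.000000 -0.219017
H 0.000000 0.000000 1.443589
H -2.162094 0.000000 0.405489
H 2.162094 -0.000000 0.405489
H -1.426254 0.000000 -1.296485
H 1.426254 -0.000000 -1.296485
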