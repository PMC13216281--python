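12
C6H6 optimized B3LYP/6-311++G(d,p)
C 1.394700 -0.000017 0.000000
H 2.479109 0.000036 0.000000
C 0.697339 1.207797 0.000000
H 1.239494 2.146958 0.000000
C -0.697329 1.207804 -0.000000
H -1.239521 2.146944 -0.000000
C -1.394699 -0.000001 -0.000000
H -2.479109 0.000045 -0.000000
C -0.697328 -1.207809 -0.000000
H -1.239508 -2.146954 -0.000000
C 0.697338 -1.207829 -0.000000
H 1.239515 -2.146976 -0.000000
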