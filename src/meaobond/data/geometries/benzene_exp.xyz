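12
C6H6 experimental r(CC)=1.397 r(CH)=1.084 (NIST CCCBDB)
C 1.397000 0.000000 0.000000
H 2.481000 0.000000 0.000000
C 0.698500 1.209837 0.000000
H 1.240500 2.148609 0.000000
C -0.698500 1.209837 0.000000
H -1.240500 2.148609 0.000000
C -1.397000 0.000000 0.000000
H -2.481000 0.000000 0.000000
C -0.698500 -1.209837 0.000000
H -1.240500 -2.148609 0.000000
C 0.698500 -1.209837 0.000000
H 1.240500 -2.148609 0.000000
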