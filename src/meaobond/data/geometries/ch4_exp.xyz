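5
CH4 experimental r(CH)=1.0870 (NIST CCCBDB)
C 0.000000 0.000000 0.000000
H 0.627580 0.627580 0.627580
H 0.627580 -0.627580 -0.627580
H -0.627580 0.627580 -0.627580
H -0.627580 -0.627580 0.627580
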