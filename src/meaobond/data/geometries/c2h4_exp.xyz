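6
C2H4 experimental r(CC)=1.339 r(CH)=1.086 HCH=117.6 (NIST CCCBDB)
C 0.669500 0.000000 0.000000
C -0.669500 0.000000 0.000000
H 1.232077 0.928926 0.000000
H 1.232077 -0.928926 0.000000
H -1.232077 0.928926 0.000000
H -1.232077 -0.928926 0.000000
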