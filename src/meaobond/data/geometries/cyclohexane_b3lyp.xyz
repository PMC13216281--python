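18
C6H12 chair optimized B3LYP/6-311++G(d,p)
C 1.466415 0.000000 0.230047
C 0.733629 1.270250 -0.227380
C -0.733629 1.270250 0.227380
C -1.466415 0.000000 -0.230047
C -0.733629 -1.270250 0.227380
C 0.733629 -1.270250 -0.227380
H 1.536449 0.000000 1.325953
H 2.494902 0.000000 -0.146216
H 0.770655 1.332149 -1.323152
H 1.247199 2.160508 0.150838
H -0.770655 1.332149 1.323152
H -1.247199 2.160508 -0.150838
H -1.536449 0.000000 -1.325953
H -2.494902 0.000000 0.146216
H -0.770655 -1.332149 1.323152
H -1.247199 -2.160508 -0.150838
H 0.770655 -1.332149 -1.323152
H 1.247199 -2.160508 0.150838
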