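2
He2 van der Waals r=2.970 (=5.612 bohr)
He 0.000000 0.000000 0.000000
He 0.000000 0.000000 2.970000
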