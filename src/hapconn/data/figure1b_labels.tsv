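vertex	haplotype
b1	b1
b2	b2
b3	b3
b4	b4
b5	b5
b6	b6
b7	b7
b8	b8
b9	b9
b10	b10
b11	b11
b12	b12
b13	b13
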