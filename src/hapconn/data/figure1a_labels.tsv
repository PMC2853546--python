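vertex	haplotype
a1	a1
a2	a2
a3	a3
a4	a4
a5	a5
a6	a6
a7	a7
a8	a8
a9	a9
a10	a10
a11	a11
a12	a12
a13	a13
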