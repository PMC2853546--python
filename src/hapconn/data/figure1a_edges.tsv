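vertex1	vertex2	length
a1	a2	1
a2	a3	1
a3	u1	1
u1	a4	1
a4	a5	1
a5	u2	1
u2	a6	1
a6	a7	1
a7	u3	1
u3	a8	1
a8	a9	1
a9	u4	1
u4	a10	1
a10	a11	1
a11	a12	1
a12	a13	1
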