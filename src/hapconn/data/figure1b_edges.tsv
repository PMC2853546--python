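vertex1	vertex2	length
b1	b2	1
b2	b3	1
b3	b4	1
b4	b5	1
b5	b6	1
b6	u1	1
u1	u2	1
u2	u3	1
u3	u4	1
u4	b8	1
b8	b7	1
b8	b9	1
b9	b10	1
b10	b11	1
b11	b12	1
b12	b13	1
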