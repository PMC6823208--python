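# Per-residue crystal <-> sequential (NCBI P24158.3) numbering map for PR3.
# Covers the surface loops whose printed ranges span equal residue counts in
# both schemes after insertion-code expansion; other residues are unmapped.
crystal_number	insertion_code	sequence_number	loop
59		73	L4A
60		74	L4A
61		75	L4A
62		76	L4A
63		77	L4A
63	A	78	L4A
63	B	79	L4A
63	C	80	L4A
75		92	L1C
76		93	L1C
77		94	L1C
78		95	L1C
79		96	L1C
92		108	L4B
93		109	L4B
94		110	L4B
95		111	L4B
96		112	L4B
97		113	L4B
98		114	L4B
99		115	L4B
110		126	L3A
111		127	L3A
112		128	L3A
113		129	L3A
114		130	L3A
115		131	L3A
116		132	L3A
117		133	L3A
124		140	L3B
125		141	L3B
126		142	L3B
127		143	L3B
128		144	L3B
129		145	L3B
130		146	L3B
131		147	L3B
132		148	L3B
133		149	L3B
192		200	L5C
193		201	L5C
194		202	L5C
202		210	L3C
203		211	L3C
204		212	L3C
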