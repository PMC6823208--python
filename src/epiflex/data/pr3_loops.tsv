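# Twelve surface loops of Proteinase 3 composing its four known epitopes.
# Ranges are inclusive; crystal numbering (PDB 1FUJ scheme, insertion codes
# honoured) is authoritative, sequential ranges (NCBI P24158.3) as printed.
name	epitope	crystal_start	crystal_end	seq_start	seq_end
L1A	1	36	38C	48	52
L1B	1	145	151	161	166
L1C	1	75	79	92	96
L3A	3	110	117	126	133
L3B	3	124	133	140	149
L3C	3	202	204	210	212
L4A	4	59	63C	73	80
L4B	4	92	99	108	115
L5A	5	165	178	180	184
L5B	5	186	187	192	195
L5C	5	192	194	200	202
L5D	5	219	224	223	229
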