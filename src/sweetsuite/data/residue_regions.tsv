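position_at	residue_at	region
57	Y	extrafacial_gate
58	G	extrafacial_gate
131	G	extrafacial_gate
191	P	extrafacial_gate
73	N	binding_pocket
192	N	binding_pocket
176	W	binding_pocket
43	P	intrafacial_gate
83	Y	intrafacial_gate
87	F	intrafacial_gate
145	P	intrafacial_gate
161	M	intrafacial_gate
162	P	intrafacial_gate
202	Q	intrafacial_gate
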