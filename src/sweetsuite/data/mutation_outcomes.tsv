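rank	relative_conservation	position_os	residue_os	position_at	residue_at	mutated_to	impact	origin
1	100	181	F	176	W	F	Abolish	Tao et al. 2015
2	77	58	C	54	S	A or C	No effect	Tao et al. 2015
3	74	61	Y	57	Y	A	Abolish	Xuan et al. 2013
4	71	150	P	145	P	A	Abolish	Tao et al. 2015
5	64	47	P	43	P	A	Abolish	Tao et al. 2015
6	59	197	N	192	N	A	Abolish	Tao et al. 2015
7	58	136	G	131	G	D	Abolish	mutagenesis survey
8	57	184	Y	179	Y	A	Reduce	Xuan et al. 2013
9	55	196	P	191	P	T	Abolish	mutagenesis survey
10	52	91	F	87	F	A	Abolish	mutagenesis survey
11	51	190	D	185	D	A	No effect	Tao et al. 2015
12	50	77	N	73	N	A	Abolish	Tao et al. 2015
13	50	207	Q	202	Q	D	Abolish	mutagenesis survey
14	49	87	Y	83	Y	A	Reduce	mutagenesis survey
15	48	166	M	161	M	A	Abolish	mutagenesis survey
16	46	62	G	58	G	D	Abolish	Xuan et al. 2013
17	45	167	P	162	P	A	Abolish	Tao et al. 2015
18	45	161	E	156	K	R	No effect	mutagenesis survey
19	45	94	Y	90	Y	A	No effect	mutagenesis survey
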