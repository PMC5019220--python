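population	n	L2'3'4+	L2a	H	HV	N	U	R	I	J1	L3	T	M	X	B	W	F	D	P	G
Esfahan	23	0	0	9	1	2	3	1	1	3	1	1	1	0	0	0	0	0	0	0
Khuzestan	23	1	0	6	0	2	3	2	0	3	2	0	1	3	0	0	0	0	0	0
Shiraz	23	0	0	5	1	3	4	0	0	2	0	4	2	0	0	2	0	0	0	0
Yazd	22	0	0	7	1	0	3	0	0	1	0	6	0	0	2	2	0	0	0	0
Mashhad	21	0	0	3	2	0	2	0	0	1	0	3	3	1	1	2	1	2	0	0
Tehran	29	0	1	9	1	0	3	0	3	4	0	2	3	0	0	1	0	0	1	1
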