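variable	stratum	n	mean	sd	median
age	16-24	63	21.81	2.18	22
age	25-29	102	27.08	1.37	27
age	30-34	108	31.85	1.41	32
age	35-39	97	36.96	1.46	37
age	40-44	49	41.39	1.32	41
age	>=45	5	45.8	1.09	45
ga	second_trimester	415	19.95	2.08	19
ga	third_trimester	9	30.44	2.00	30
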