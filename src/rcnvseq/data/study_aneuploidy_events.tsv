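chrom	zone	g_notation	n	mosaic
chr7	dup(7)(p22.3q36.3)(mos)	chr7:g.1_159138663dup	1	1
chr13	dup(13)(q12.11q34)	chr13:g.19500000_115169878dup	9	0
chr13	dup(13)(q12.11q34)(mos)	chr13:g.19500000_115169878dup	1	1
chr15	dup(15)(q11.1q26.3)(mos)	chr15:g.20700000_102531392dup	2	1
chr18	dup(18)(p11.32q23)	chr18:g.1_78077248dup	24	0
chr21	dup(21)(q11.2q22.3)	chr21:g.14300000_48129895dup	147	0
chr21	dup(21)(q11.1q22.3)	chr21:g.14300000_48129895dup	16	0
chr21	dup(21)(q11.2q22.3)(mos)	chr21:g.14300000_48129895dup	6	1
chrX	dup(X)(p22.33q28)	chrX:g.1_155270560dup	44	0
chrX	dup(X)(p22.33q28)(mos)	chrX:g.1_155270560dup	6	1
chrX	del(X)(p22.33q28)	chrX:g.1_155270560del	9	0
chrX	del(X)(p22.33q28)(mos)	chrX:g.1_155270560del	13	1
chrY	dup(Y)(p11.32q12)	chrY:g.1_59373566dup	16	0
chrY	dup(Y)(p11.32q12)(mos)	chrY:g.1_59373566dup	3	1
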