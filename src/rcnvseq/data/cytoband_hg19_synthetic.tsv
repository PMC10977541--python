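#chrom	start	end	band	stain
chr1	0	7200000	p36.3	gneg
chr1	7200000	28000000	p36.1	gpos50
chr1	28000000	34600000	p35	gneg
chr1	34600000	46300000	p34	gpos50
chr1	46300000	56100000	p32	gneg
chr1	56100000	68900000	p31	gpos50
chr1	68900000	84900000	p22	gneg
chr1	84900000	107200000	p21	gpos50
chr1	107200000	116100000	p13	gneg
chr1	116100000	120500000	p12	gpos50
chr1	120500000	125000000	p11	acen
chr1	125000000	128600000	q11	acen
chr1	128600000	142600000	q12	gvar
chr1	142600000	155100000	q21	gneg
chr1	155100000	165500000	q23	gpos50
chr1	165500000	180300000	q25	gneg
chr1	180300000	190800000	q31	gpos50
chr1	190800000	207200000	q32	gneg
chr1	207200000	214400000	q41	gpos50
chr1	214400000	224100000	q42	gneg
chr1	224100000	236600000	q43	gpos50
chr1	236600000	249250621	q44	gneg
chr2	0	23300000	p25.3	gneg
chr2	23300000	74600000	p16	gpos50
chr2	74600000	93300000	p11.2	acen
chr2	93300000	108300000	q11.2	acen
chr2	108300000	198200000	q22	gpos50
chr2	198200000	243199373	q37.3	gneg
chr3	0	22800000	p26.3	gneg
chr3	22800000	72800000	p21	gpos50
chr3	72800000	91000000	p11.1	acen
chr3	91000000	101700000	q11.2	acen
chr3	101700000	165900000	q21	gpos50
chr3	165900000	198022430	q29	gneg
chr4	0	12600000	p16.3	gneg
chr4	12600000	40300000	p15	gpos50
chr4	40300000	50400000	p11	acen
chr4	50400000	64500000	q11	acen
chr4	64500000	148900000	q22	gpos50
chr4	148900000	191154276	q35.2	gneg
chr5	0	12100000	p15.33	gneg
chr5	12100000	38700000	p14	gpos50
chr5	38700000	48400000	p11	acen
chr5	48400000	61700000	q11.2	acen
chr5	61700000	141200000	q21	gpos50
chr5	141200000	180915260	q35.3	gneg
chr6	0	15200000	p25.3	gneg
chr6	15200000	48800000	p21	gpos50
chr6	48800000	61000000	p11.1	acen
chr6	61000000	72000000	q11.1	acen
chr6	72000000	138100000	q16	gpos50
chr6	138100000	171115067	q27	gneg
chr7	0	2800000	p22.3	gneg
chr7	2800000	7300000	p22.1	gpos50
chr7	7300000	28000000	p21	gneg
chr7	28000000	37200000	p15	gpos50
chr7	37200000	45400000	p14	gneg
chr7	45400000	50500000	p13	gpos50
chr7	50500000	58000000	p12	gneg
chr7	58000000	59900000	p11.1	acen
chr7	59900000	61700000	q11.1	acen
chr7	61700000	77500000	q11.2	gneg
chr7	77500000	98000000	q21	gpos50
chr7	98000000	107400000	q22	gneg
chr7	107400000	127500000	q31	gpos50
chr7	127500000	138200000	q32	gneg
chr7	138200000	143100000	q33	gpos50
chr7	143100000	147900000	q34	gneg
chr7	147900000	152600000	q35	gpos50
chr7	152600000	155100000	q36.1	gneg
chr7	155100000	156500000	q36.2	gpos25
chr7	156500000	159138663	q36.3	gneg
chr8	0	11400000	p23.3	gneg
chr8	11400000	36500000	p21	gpos50
chr8	36500000	45600000	p11.1	acen
chr8	45600000	55700000	q11.1	acen
chr8	55700000	116100000	q21	gpos50
chr8	116100000	146364022	q24.3	gneg
chr9	0	12200000	p24.3	gneg
chr9	12200000	39200000	p21	gpos50
chr9	39200000	49000000	p11.1	acen
chr9	49000000	58200000	q11	acen
chr9	58200000	113500000	q21	gpos50
chr9	113500000	141213431	q34.3	gneg
chr10	0	10000000	p15.3	gneg
chr10	10000000	32200000	p12	gpos50
chr10	32200000	40200000	p11.1	acen
chr10	40200000	49700000	q11.1	acen
chr10	49700000	106900000	q21	gpos50
chr10	106900000	135534747	q26.3	gneg
chr11	0	13400000	p15.5	gneg
chr11	13400000	43000000	p13	gpos50
chr11	43000000	53700000	p11.11	acen
chr11	53700000	61800000	q11	acen
chr11	61800000	110600000	q14	gpos50
chr11	110600000	135006516	q25	gneg
chr12	0	9000000	p13.33	gneg
chr12	9000000	28600000	p12	gpos50
chr12	28600000	35800000	p11.1	acen
chr12	35800000	45600000	q11	acen
chr12	45600000	104400000	q21	gpos50
chr12	104400000	133851895	q24.33	gneg
chr13	0	4500000	p13	gvar
chr13	4500000	10000000	p12	stalk
chr13	10000000	16300000	p11.2	gvar
chr13	16300000	17900000	p11.1	acen
chr13	17900000	19500000	q11	acen
chr13	19500000	23300000	q12.11	gneg
chr13	23300000	31600000	q12.2	gpos50
chr13	31600000	40100000	q14	gneg
chr13	40100000	59600000	q21	gpos50
chr13	59600000	73300000	q22	gneg
chr13	73300000	87700000	q31	gpos50
chr13	87700000	97000000	q32	gneg
chr13	97000000	109600000	q33	gpos50
chr13	109600000	115169878	q34	gneg
chr14	0	4400000	p13	gneg
chr14	4400000	14100000	p11.2	gpos50
chr14	14100000	17600000	p11.1	acen
chr14	17600000	26600000	q11.1	acen
chr14	26600000	80400000	q21	gpos50
chr14	80400000	107349540	q32.33	gneg
chr15	0	3900000	p13	gvar
chr15	3900000	8700000	p12	stalk
chr15	8700000	15300000	p11.2	gvar
chr15	15300000	18400000	p11.1	acen
chr15	18400000	20700000	q11.1	acen
chr15	20700000	25700000	q11.2	gneg
chr15	25700000	33400000	q13	gpos50
chr15	33400000	39800000	q14	gneg
chr15	39800000	44500000	q15	gpos50
chr15	44500000	59100000	q21	gneg
chr15	59100000	67400000	q22	gpos50
chr15	67400000	73300000	q23	gneg
chr15	73300000	78500000	q24	gpos50
chr15	78500000	89100000	q25	gneg
chr15	89100000	94300000	q26.1	gpos50
chr15	94300000	98500000	q26.2	gneg
chr15	98500000	102531392	q26.3	gpos50
chr16	0	9200000	p13.3	gneg
chr16	9200000	29300000	p12	gpos50
chr16	29300000	36600000	p11.1	acen
chr16	36600000	42000000	q11.1	acen
chr16	42000000	74200000	q21	gpos50
chr16	74200000	90354753	q24.3	gneg
chr17	0	6000000	p13.3	gneg
chr17	6000000	19200000	p12	gpos50
chr17	19200000	24000000	p11.1	acen
chr17	24000000	29700000	q11.1	acen
chr17	29700000	64000000	q21	gpos50
chr17	64000000	81195210	q25.3	gneg
chr18	0	2900000	p11.32	gneg
chr18	2900000	7100000	p11.31	gpos50
chr18	7100000	15400000	p11.2	gneg
chr18	15400000	17200000	p11.1	acen
chr18	17200000	19000000	q11.1	acen
chr18	19000000	25000000	q11.2	gneg
chr18	25000000	39500000	q12	gpos50
chr18	39500000	56200000	q21	gneg
chr18	56200000	73100000	q22	gpos50
chr18	73100000	78077248	q23	gneg
chr19	0	6600000	p13.3	gneg
chr19	6600000	21200000	p12	gpos50
chr19	21200000	26500000	p11	acen
chr19	26500000	29800000	q11	acen
chr19	29800000	49300000	q13.1	gpos50
chr19	49300000	59128983	q13.43	gneg
chr20	0	6900000	p13	gneg
chr20	6900000	22000000	p12	gpos50
chr20	22000000	27500000	p11.1	acen
chr20	27500000	31100000	q11.1	acen
chr20	31100000	52400000	q13.1	gpos50
chr20	52400000	63025520	q13.33	gneg
chr21	0	2800000	p13	gvar
chr21	2800000	6800000	p12	stalk
chr21	6800000	10900000	p11.2	gvar
chr21	10900000	13200000	p11.1	acen
chr21	13200000	14300000	q11.1	acen
chr21	14300000	16400000	q11.2	gneg
chr21	16400000	30200000	q21	gpos50
chr21	30200000	38300000	q22.1	gneg
chr21	38300000	41200000	q22.2	gpos50
chr21	41200000	48129895	q22.3	gneg
chr22	0	3700000	p13	gneg
chr22	3700000	11800000	p12	gpos50
chr22	11800000	14700000	p11.1	acen
chr22	14700000	18400000	q11.1	acen
chr22	18400000	40300000	q12	gpos50
chr22	40300000	51304566	q13.33	gneg
chrX	0	4300000	p22.33	gneg
chrX	4300000	6000000	p22.32	gpos50
chrX	6000000	9500000	p22.31	gneg
chrX	9500000	17100000	p22.2	gpos50
chrX	17100000	37600000	p21	gneg
chrX	37600000	46400000	p11.4	gpos50
chrX	46400000	58100000	p11.2	gneg
chrX	58100000	60600000	p11.1	acen
chrX	60600000	65000000	q11	acen
chrX	65000000	76800000	q21	gpos50
chrX	76800000	89400000	q22	gneg
chrX	89400000	99100000	q23	gpos50
chrX	99100000	108300000	q24	gneg
chrX	108300000	118300000	q25	gpos50
chrX	118300000	130400000	q26	gneg
chrX	130400000	147100000	q27	gpos50
chrX	147100000	155270560	q28	gneg
chrY	0	2500000	p11.32	gneg
chrY	2500000	6600000	p11.31	gpos50
chrY	6600000	11600000	p11.2	gneg
chrY	11600000	12500000	p11.1	acen
chrY	12500000	13400000	q11.1	acen
chrY	13400000	14300000	q11.21	gneg
chrY	14300000	19600000	q11.22	gpos50
chrY	19600000	28800000	q11.23	gneg
chrY	28800000	59373566	q12	gvar
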