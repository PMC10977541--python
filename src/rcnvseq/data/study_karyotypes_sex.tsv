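group	karyotype	n
klinefelter	47,XXY	19
klinefelter	47,XXY,15ps+	1
klinefelter_mos	47,XXY[]/46,XY[]	5
jacob	47,XYY	13
superman	48,XYYY	1
triple_x	47,XXX	10
triple_x	47,XXX,1qh+,22ps+	1
triple_x	47,XXX[56]/45,X0[6]	1
turner	45,X0	5
turner	45,XY,rob(15;22)	1
turner	46,X,+mar[14]/45,X[56]	1
turner_mos	45,XO[]/46,XX[]	10
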