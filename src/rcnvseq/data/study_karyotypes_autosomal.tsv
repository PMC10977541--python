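group	karyotype	n
trisomy_21	47,XY+21	66
trisomy_21	47,XX+21	53
trisomy_21	46,XX+21,rob(15;22)	1
trisomy_21	46,XX,rob(21;21)+21	1
trisomy_21	47,XX+21,t(9;15)	1
trisomy_21	47,XX,inv(9)+21	1
trisomy_21	47,XX,14ps+,+21	1
trisomy_21	46,XY,rob(15;22)+21	1
trisomy_21	46,XY,rob(14;21)+21	1
trisomy_21_mos	47,XY+21[]/46,XY[]	3
trisomy_21_mos	47,XX+21[]/46,XX[]	1
trisomy_18	47,XX+18	12
trisomy_18	47,XY+18	6
trisomy_18	47,XY+18,t(2;7)	1
trisomy_13	47,XY+13	3
trisomy_13	47,XX+13	2
trisomy_13	46,XY,rob(13;13)+13	1
trisomy_13_mos	47,XX+13[46]/46,XX[26]	1
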