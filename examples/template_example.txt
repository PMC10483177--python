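Volume	UV 280	UV 260	Fraction start	Fraction
ml	mAU	mAU	ml	(Fractions)
0.0	0.0	0.0	0.0	1
1.0	0.0	0.0	1.0	2
2.0	0.0	0.0		
3.0	0.0	0.0		
4.0	0.0	0.0		
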