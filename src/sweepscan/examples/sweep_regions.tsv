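chrom	start	end	length
LG1 (LG6)	220001	600000	380000
LG1 (LG6)	14220001	14330000	110000
LG1 (LG6)	8850001	9010000	160000
LG2 (LG1)	19350001	19480000	130000
LG2 (LG1)	2760001	2880000	120000
LG3 (LG4)	7500001	7670000	170000
LG4 (LG3)	17930001	18040000	110000
LG4 (LG3)	10790001	10930000	140000
LG4 (LG3)	17240001	17430000	190000
LG4 (LG3)	2150001	2250000	100000
LG5 (LG2)	24700001	24910000	210000
LG5 (LG2)	4060001	4220000	160000
LG5 (LG2)	8300001	8400000	100000
LG6 (LG8)	18730001	18880000	150000
LG6 (LG8)	12980001	13120000	140000
LG6 (LG8)	1840001	1940000	100000
LG7 (LG5)	7390001	7530000	140000
LG7 (LG5)	1900001	2000000	100000
LG8 (LG7)	3670001	3840000	170000
LG8 (LG7)	3340001	3570000	230000
LG8 (LG7)	1900001	2440000	540000
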