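# id: M1
# name: A-philicity
# units: relative A-form propensity
# citation: Ivanov & Minchenkova (1994) Mol Biol 28:1258-1271
# confidence: secondary-compilation (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	1.04
AC	2.97
AG	1.62
AT	0.57
CA	0.89
CC	2.5
CG	2.36
CT	1.62
GA	1.45
GC	3.67
GG	2.5
GT	2.97
TA	0.32
TC	1.45
TG	0.89
TT	1.04
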