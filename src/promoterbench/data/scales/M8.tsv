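# id: M8
# name: duplex stability free energy
# units: kcal/mol (deltaG37, nearest neighbor)
# citation: SantaLucia et al. (1996) Biochemistry 35:3555-3562
# confidence: primary (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	-1.0
AC	-1.44
AG	-1.28
AT	-0.88
CA	-1.45
CC	-1.84
CG	-2.17
CT	-1.28
GA	-1.3
GC	-2.24
GG	-1.84
GT	-1.44
TA	-0.58
TC	-1.3
TG	-1.45
TT	-1.0
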