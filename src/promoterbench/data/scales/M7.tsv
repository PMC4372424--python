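# id: M7
# name: duplex disruption free energy
# units: kcal/mol
# citation: Breslauer et al. (1986) PNAS 83:3746-3750
# confidence: primary (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	1.9
AC	1.3
AG	1.6
AT	1.5
CA	1.9
CC	3.1
CG	3.6
CT	1.6
GA	1.6
GC	3.1
GG	3.1
GT	1.3
TA	0.9
TC	1.6
TG	1.9
TT	1.9
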