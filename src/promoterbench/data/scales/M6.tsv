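# id: M6
# name: Z-DNA free energy
# units: kcal/mol (B-to-Z transition)
# citation: Ho et al. (1986) EMBO J 5:2737-2744
# confidence: primary (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	3.9
AC	4.6
AG	3.4
AT	5.9
CA	1.3
CC	2.4
CG	0.7
CT	3.4
GA	3.4
GC	4.0
GG	2.4
GT	4.6
TA	2.5
TC	3.4
TG	1.3
TT	3.9
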