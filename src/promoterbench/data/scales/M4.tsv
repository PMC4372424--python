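# id: M4
# name: DNA bending stiffness
# units: force constant (arbitrary)
# citation: Sivolob & Khrapunov (1995) J Mol Biol 247:918-931
# confidence: primary (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	35
AC	60
AG	60
AT	20
CA	60
CC	130
CG	85
CT	60
GA	60
GC	85
GG	130
GT	60
TA	20
TC	60
TG	60
TT	35
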