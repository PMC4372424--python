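# id: M10
# name: propeller twist
# units: degrees
# citation: el Hassan & Calladine (1996) J Mol Biol 259:95-103
# confidence: secondary-compilation (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	-18.66
AC	-13.1
AG	-14.0
AT	-15.01
CA	-9.45
CC	-8.11
CG	-10.03
CT	-14.0
GA	-13.48
GC	-11.08
GG	-8.11
GT	-13.1
TA	-11.85
TC	-13.48
TG	-9.45
TT	-18.66
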