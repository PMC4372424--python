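# id: M5
# name: DNA denaturation temperature
# units: degrees C (dinucleotide stability)
# citation: Blake & Delcourt (1998) Nucleic Acids Res 26:3323-3332
# confidence: secondary-compilation (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	66.51
AC	108.8
AG	85.12
AT	72.29
CA	64.92
CC	99.31
CG	106.7
CT	85.12
GA	89.85
GC	136.3
GG	99.31
GT	108.8
TA	50.11
TC	89.85
TG	64.92
TT	66.51
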