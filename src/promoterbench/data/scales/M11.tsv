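# id: M11
# name: protein-induced DNA twist
# units: degrees (protein-DNA complex steps)
# citation: Olson et al. (1998) PNAS 95:11163-11168
# confidence: secondary-compilation (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	35.3
AC	32.5
AG	32.0
AT	29.8
CA	36.9
CC	33.1
CG	35.6
CT	32.0
GA	36.1
GC	33.8
GG	33.1
GT	32.5
TA	37.1
TC	36.1
TG	36.9
TT	35.3
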