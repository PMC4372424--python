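# id: M3
# name: Olson B-DNA twist
# units: degrees
# citation: Olson et al. (1998) PNAS 95:11163-11168 (B-DNA crystal steps)
# confidence: secondary-compilation (values transcribed from the cited primary source; sign/unit conventions can differ across editions)
dinucleotide	value
AA	35.1
AC	31.5
AG	31.9
AT	29.3
CA	37.3
CC	32.9
CG	36.1
CT	31.9
GA	36.3
GC	33.6
GG	32.9
GT	31.5
TA	37.8
TC	36.3
TG	37.3
TT	35.1
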