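marker	S44	JL14	JL40	JC8	JC9	JC12	JC13	DS1	D4	DF1	DF2
narG	1	1	1	1	1	1	1	1	1	1	1
narH	1	1	1	1	1	1	1	1	1	1	1
narI	1	1	1	1	1	1	1	1	1	1	1
ureC	1	1	1	1	1	1	1	1	1	1	1
tesB	1	1	1	1	1	1	1	1	1	1	1
tesD	1	1	1	1	1	1	1	1	1	1	1
pcaI	1	1	1	1	1	1	1	1	1	1	1
pcaJ	1	1	1	1	1	1	1	1	1	1	1
mdh	1	1	1	1	1	1	1	1	1	1	1
gntK	1	1	1	1	1	1	1	1	1	1	1
acs	1	1	1	1	1	1	1	1	1	1	1
lldD	1	1	1	1	1	1	1	1	1	1	1
pobA	1	1	1	1	1	1	1	1	1	1	1
ligA	1	1	1	1	1	1	1	1	1	1	1
ligB	1	1	1	1	1	1	1	1	1	1	1
gltA	1	1	1	1	1	1	1	1	1	1	1
citT	1	1	1	1	1	1	1	1	1	1	1
fadD	1	1	1	1	1	1	1	1	1	1	1
ampC	1	1	1	1	1	1	1	1	1	1	1
blaOXA	1	1	1	1	1	1	1	1	1	1	1
ampR	1	1	1	1	1	1	1	1	1	1	1
cutE	1	1	1	1	1	1	1	1	1	1	1
copA	1	1	1	1	1	1	1	1	1	1	1
zntA	1	1	1	1	1	1	1	1	1	1	1
czcA	1	1	1	1	1	1	1	1	1	1	1
tnaA	0	0	0	0	0	0	0	0	0	0	0
bglB	0	0	0	0	0	0	0	0	0	0	0
gelE	0	0	0	0	0	0	0	0	0	0	0
lacZ	0	0	0	0	0	0	0	0	0	0	0
glf	0	0	0	0	0	0	0	0	0	0	0
glk	0	0	0	0	0	0	0	0	0	0	0
araA	0	0	0	0	0	0	0	0	0	0	0
manA	0	0	0	0	0	0	0	0	0	0	0
mtlD	0	0	0	0	0	0	0	0	0	0	0
nagK	0	0	0	0	0	0	0	0	0	0	0
malZ	0	0	0	0	0	0	0	0	0	0	0
tetA	0	0	0	0	0	0	0	0	0	0	0
merA	1	1	1	0	0	0	0	1	0	1	1
merR	1	1	1	0	0	0	0	1	0	1	1
arcA	0	0	0	0	0	0	0	0	0	0	0
aphA	0	0	0	0	0	0	0	0	0	0	0
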