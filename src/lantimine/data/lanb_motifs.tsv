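name	pattern	ref_start	ref_end	kind
YxxR	YxxR	80	83	motif
RxTPFG	RxTPFG	87	92	motif
FxxxYG	FxxxYG	342	347	motif
GxG	GxG	363	365	motif
GRF	GRF	463	465	motif
PxxxRxxNV	PxxxRxxNV	501	509	motif
RFL	RFL	585	587	motif
RYG	RYG	826	828	motif
HxxxNR	HxxxNR	961	966	motif
R14	R	14	14	residue
D121	D	121	121	residue
N145	N	145	145	residue
L217	L	217	217	residue
D299	D	299	299	residue
V352	V	352	352	residue
P612	P	612	612	residue
W616	W	616	616	residue
P639	P	639	639	residue
D648	D	648	648	residue
F840	F	840	840	residue
D843	D	843	843	residue
E975	E	975	975	residue
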