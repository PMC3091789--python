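name	pattern	ref_start	ref_end	kind
LxxG	LxxG	39	42	motif
YDxxxGxxG	YDxxxGxxG	140	148	motif
GxAHGxxG	GxAHGxxG	209	216	motif
WCYG	WCYG	283	286	motif
CHG	CHG	330	332	motif
GxxxGxxGxxLxL	GxxxGxxGxxLxL	377	389	motif
G90	G	90	90	residue
W258	W	258	258	residue
R280	R	280	280	residue
G289	G	289	289	residue
W401	W	401	401	residue
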