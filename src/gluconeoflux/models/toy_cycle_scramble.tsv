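#! {"species": "toy_cycle_scramble", "note": "Closed cycle with a rotationally symmetric intermediate (50/50 scrambling), cleavage and re-condensation; 8 carbons total."}
# id	equation	atom_map	reversible	kind	nadh_uqh2	nadph	atp	pathway
UPT	1 X_EXT -> 1 A	X_EXT:ab -> A:ab	0	uptake	0	0	0	UPT
W1	1 A -> 1 B	A:ab -> B:ab; A:ab -> B:ba	0	internal	0	0	0	X
W2	1 B -> 1 C + 1 D	B:ab -> C:a + D:b	0	internal	0	0	0	X
W3	1 C + 1 D -> 1 E	C:a + D:b -> E:ba	0	internal	0	0	0	X
W4	1 E -> 1 A	E:ab -> A:ab	0	internal	0	0	0	X
OUT	1 E -> 1 E_EXT	E:ab -> E_EXT:ab	0	secretion	0	0	0	OUT
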