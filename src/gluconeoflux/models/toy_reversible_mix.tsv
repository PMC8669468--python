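#! {"species": "toy_reversible_mix", "note": "Two differently ordered routes into one pool joined by a reversible bridge, so exchange flux shifts the observable labeling; 12 carbons total."}
# id	equation	atom_map	reversible	kind	nadh_uqh2	nadph	atp	pathway
UPT	1 A_EXT -> 1 A	A_EXT:abc -> A:abc	0	uptake	0	0	0	UPT
U1	1 A -> 1 B	A:abc -> B:abc	0	internal	0	0	0	X
U2	1 A -> 1 C + 1 D	A:abc -> C:ab + D:c	0	internal	0	0	0	X
U3	1 C + 1 D -> 1 E	C:ab + D:c -> E:cab	0	internal	0	0	0	X
U4	1 B -> 1 E	B:abc -> E:abc	1	internal	0	0	0	X
OUT	1 E -> 1 E_EXT	E:abc -> E_EXT:abc	0	secretion	0	0	0	OUT
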