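#! {"species": "toy_chain_split", "note": "Cleavage, condensation and a twisted recycle loop; 12 carbons total. Used for EMU-vs-isotopomer equivalence checks."}
# id	equation	atom_map	reversible	kind	nadh_uqh2	nadph	atp	pathway
UPT	1 A_EXT -> 1 A	A_EXT:abc -> A:abc	0	uptake	0	0	0	UPT
V1	1 A -> 1 B + 1 C	A:abc -> B:ab + C:c	0	internal	0	0	0	X
V2	1 B -> 1 D	B:ab -> D:ab	0	internal	0	0	0	X
V3	1 C -> 1 E	C:a -> E:a	0	internal	0	0	0	X
V4	1 D + 1 E -> 1 F	D:ab + E:c -> F:abc	0	internal	0	0	0	X
V5	1 F -> 1 B + 1 C	F:abc -> B:bc + C:a	0	internal	0	0	0	X
OUT	1 F -> 1 F_EXT	F:abc -> F_EXT:abc	0	secretion	0	0	0	OUT
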