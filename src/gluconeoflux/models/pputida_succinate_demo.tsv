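#! {"species": "P_putida_demo", "substrate": "succinate", "normalization": "uptake=100", "note": "Condensed P. putida-topology benchmark: TCA cycle with scrambling at the symmetric C4 acids, glyoxylate shunt, PEP carboxykinase cataplerosis, malic enzyme, gluconeogenic EMP to G6P, CO2 pool, optional unlabeled malate carry-over and six biomass drains. Reactions are oriented irreversibly in the physiological direction so that every free flux is identifiable from the two succinate tracers."}
# id	equation	atom_map	reversible	kind	nadh_uqh2	nadph	atp	pathway
UPT	1 SUC_EXT -> 1 SUC	SUC_EXT:abcd -> SUC:abcd; SUC_EXT:abcd -> SUC:dcba	0	uptake	0	0	0	UPT
SDH	1 SUC -> 1 FUM	SUC:abcd -> FUM:abcd; SUC:abcd -> FUM:dcba	0	internal	1	0	0	TCA
FUMA	1 FUM -> 1 MAL	FUM:abcd -> MAL:abcd	0	internal	0	0	0	TCA
MDH	1 MAL -> 1 OAA	MAL:abcd -> OAA:abcd	0	internal	1	0	0	TCA
CS	1 OAA + 1 ACCOA -> 1 CIT	OAA:abcd + ACCOA:ef -> CIT:abcdfe	0	internal	0	0	0	TCA
ICD	1 CIT -> 1 AKG + 1 CO2	CIT:abcdef -> AKG:dcbef + CO2:a	0	internal	0	1	0	TCA
AKGX	1 AKG -> 1 SUC + 1 CO2	AKG:abcde -> SUC:bcde + CO2:a; AKG:abcde -> SUC:edcb + CO2:a	0	internal	1	0	1	TCA
ICL	1 CIT -> 1 SUC + 1 GLX	CIT:abcdef -> SUC:abef + GLX:dc; CIT:abcdef -> SUC:feba + GLX:dc	0	internal	0	0	0	GLX
MS	1 GLX + 1 ACCOA -> 1 MAL	GLX:ab + ACCOA:cd -> MAL:abdc	0	internal	0	0	0	GLX
PCK	1 OAA -> 1 PEP + 1 CO2	OAA:abcd -> PEP:abc + CO2:d	0	internal	0	0	-1	ANA
ME	1 MAL -> 1 PYR + 1 CO2	MAL:abcd -> PYR:abc + CO2:d	0	internal	0	1	0	ANA
PDH	1 PYR -> 1 ACCOA + 1 CO2	PYR:abc -> ACCOA:bc + CO2:a	0	internal	1	0	0	TCA
ENO	1 PEP -> 1 PG3	PEP:abc -> PG3:abc	0	internal	0	0	0	EMP
TRI	1 PG3 -> 1 GAP	PG3:abc -> GAP:abc	0	internal	-1	-1	0	EMP
TPI	1 GAP -> 1 DHAP	GAP:abc -> DHAP:cba	0	internal	0	0	0	EMP
HEX	1 DHAP + 1 GAP -> 1 F6P	DHAP:abc + GAP:def -> F6P:abcdef	0	internal	0	0	0	EMP
PGI	1 F6P -> 1 G6P	F6P:abcdef -> G6P:abcdef	0	internal	0	0	0	EMP
CO2_OUT	1 CO2 -> 1 CO2_EXT	CO2:a -> CO2_EXT:a	0	secretion	0	0	0	OUT
MAL_IN	- -> 1 MAL	-	0	unlabeled_influx	0	0	0	IN
BM_OAA	1 OAA -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_AKG	1 AKG -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_PYR	1 PYR -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_ACCOA	1 ACCOA -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_PG3	1 PG3 -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_G6P	1 G6P -> -	-	0	biomass_drain	0	0	0	BIOMASS
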