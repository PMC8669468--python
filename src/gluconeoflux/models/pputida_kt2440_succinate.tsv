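#! {"species": "P_putida_KT2440", "substrate": "succinate", "normalization": "uptake=100", "note": "Reconstruction of central carbon metabolism during gluconeogenic growth on succinate: C4-dicarboxylate uptake, TCA cycle, glyoxylate shunt, anaplerosis/cataplerosis, gluconeogenic EMP, oxidative/non-oxidative PP, ED pathway, two transhydrogenases, CO2 pool, unlabeled carry-over influxes and biomass drains. Granularity: PGM/ENO split, GAPDH+PGK lumped, EDD/EDA explicit, aspartate as OAA proxy; 63 reactions."}
# id	equation	atom_map	reversible	kind	nadh_uqh2	nadph	atp	pathway
SUC_UPT	1 SUC_EXT -> 1 SUC	SUC_EXT:abcd -> SUC:abcd; SUC_EXT:abcd -> SUC:dcba	0	uptake	0	0	0	UPT
SDH	1 SUC -> 1 FUM	SUC:abcd -> FUM:abcd; SUC:abcd -> FUM:dcba	0	internal	1	0	0	TCA
FUMA	1 FUM -> 1 MAL	FUM:abcd -> MAL:abcd	1	internal	0	0	0	TCA
MDH	1 MAL -> 1 OAA	MAL:abcd -> OAA:abcd	1	internal	1	0	0	TCA
MQO	1 MAL -> 1 OAA	MAL:abcd -> OAA:abcd	0	internal	1	0	0	TCA
CS	1 OAA + 1 ACCOA -> 1 CIT	OAA:abcd + ACCOA:ef -> CIT:abcdfe	0	internal	0	0	0	TCA
ACN	1 CIT -> 1 ICT	CIT:abcdef -> ICT:abcdef	1	internal	0	0	0	TCA
ICD	1 ICT -> 1 AKG + 1 CO2	ICT:abcdef -> AKG:dcbef + CO2:a	0	internal	0	1	0	TCA
AKGDH	1 AKG -> 1 SUCCOA + 1 CO2	AKG:abcde -> SUCCOA:bcde + CO2:a	0	internal	1	0	0	TCA
SCS	1 SUCCOA -> 1 SUC	SUCCOA:abcd -> SUC:abcd; SUCCOA:abcd -> SUC:dcba	1	internal	0	0	1	TCA
ICL	1 ICT -> 1 SUC + 1 GLX	ICT:abcdef -> SUC:abef + GLX:dc; ICT:abcdef -> SUC:feba + GLX:dc	0	internal	0	0	0	GLX
MS	1 GLX + 1 ACCOA -> 1 MAL	GLX:ab + ACCOA:cd -> MAL:abdc	0	internal	0	0	0	GLX
PCK	1 OAA -> 1 PEP + 1 CO2	OAA:abcd -> PEP:abc + CO2:d	0	internal	0	0	-1	ANA
PPC	1 PEP + 1 CO2 -> 1 OAA	PEP:abc + CO2:d -> OAA:abcd	0	internal	0	0	0	ANA
PC	1 PYR + 1 CO2 -> 1 OAA	PYR:abc + CO2:d -> OAA:abcd	0	internal	0	0	-1	ANA
ME	1 MAL -> 1 PYR + 1 CO2	MAL:abcd -> PYR:abc + CO2:d	0	internal	0	1	0	ANA
ODX	1 OAA -> 1 PYR + 1 CO2	OAA:abcd -> PYR:abc + CO2:d	0	internal	0	0	0	ANA
PDH	1 PYR -> 1 ACCOA + 1 CO2	PYR:abc -> ACCOA:bc + CO2:a	0	internal	1	0	0	TCA
PYK	1 PEP -> 1 PYR	PEP:abc -> PYR:abc	0	internal	0	0	1	EMP
PPS	1 PYR -> 1 PEP	PYR:abc -> PEP:abc	0	internal	0	0	-2	EMP
ENO	1 PG2 -> 1 PEP	PG2:abc -> PEP:abc	1	internal	0	0	0	EMP
PGM	1 PG3 -> 1 PG2	PG3:abc -> PG2:abc	1	internal	0	0	0	EMP
GAPDH	1 GAP -> 1 PG3	GAP:abc -> PG3:abc	1	internal	1	0	1	EMP
TPI	1 DHAP -> 1 GAP	DHAP:abc -> GAP:cba	1	internal	0	0	0	EMP
FBA	1 DHAP + 1 GAP -> 1 FBP	DHAP:abc + GAP:def -> FBP:abcdef	1	internal	0	0	0	EMP
FBP	1 FBP -> 1 F6P	FBP:abcdef -> F6P:abcdef	0	internal	0	0	0	EMP
PGI	1 F6P -> 1 G6P	F6P:abcdef -> G6P:abcdef	1	internal	0	0	0	EMP
PGMU	1 G6P -> 1 G1P	G6P:abcdef -> G1P:abcdef	1	internal	0	0	0	EMP
G6PDH	1 G6P -> 1 PG6	G6P:abcdef -> PG6:abcdef	0	internal	0	1	0	PP
GND	1 PG6 -> 1 RU5P + 1 CO2	PG6:abcdef -> RU5P:bcdef + CO2:a	0	internal	0	1	0	PP
EDD	1 PG6 -> 1 KDPG	PG6:abcdef -> KDPG:abcdef	0	internal	0	0	0	ED
EDA	1 KDPG -> 1 PYR + 1 GAP	KDPG:abcdef -> PYR:abc + GAP:def	0	internal	0	0	0	ED
RPI	1 RU5P -> 1 R5P	RU5P:abcde -> R5P:abcde	1	internal	0	0	0	PP
RPE	1 RU5P -> 1 X5P	RU5P:abcde -> X5P:abcde	1	internal	0	0	0	PP
TKT1	1 X5P + 1 R5P -> 1 S7P + 1 GAP	X5P:abcde + R5P:fghij -> S7P:abfghij + GAP:cde	1	internal	0	0	0	PP
TAL	1 S7P + 1 GAP -> 1 F6P + 1 E4P	S7P:abcdefg + GAP:hij -> F6P:abchij + E4P:defg	1	internal	0	0	0	PP
TKT2	1 X5P + 1 E4P -> 1 F6P + 1 GAP	X5P:abcde + E4P:fghi -> F6P:abfghi + GAP:cde	1	internal	0	0	0	PP
ASPS	1 OAA -> 1 ASP	OAA:abcd -> ASP:abcd	0	internal	0	0	0	TCA
THD_PNT	- -> -	-	0	internal	-1	1	0	THD
THD_STH	- -> -	-	0	internal	1	-1	0	THD
CO2_OUT	1 CO2 -> 1 CO2_EXT	CO2:a -> CO2_EXT:a	0	secretion	0	0	0	OUT
CO2_IN	- -> 1 CO2	-	0	unlabeled_influx	0	0	0	IN
ACE_SEC	1 ACCOA -> 1 ACE_EXT	ACCOA:ab -> ACE_EXT:ab	0	secretion	0	0	1	OUT
MAL_IN	- -> 1 MAL	-	0	unlabeled_influx	0	0	0	IN
PYR_IN	- -> 1 PYR	-	0	unlabeled_influx	0	0	0	IN
G6P_IN	- -> 1 G6P	-	0	unlabeled_influx	0	0	0	IN
DHAP_IN	- -> 1 DHAP	-	0	unlabeled_influx	0	0	0	IN
ACCOA_IN	- -> 1 ACCOA	-	0	unlabeled_influx	0	0	0	IN
BM_G6P	1 G6P -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_F6P	1 F6P -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_G1P	1 G1P -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_R5P	1 R5P -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_E4P	1 E4P -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_GAP	1 GAP -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_PG3	1 PG3 -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_PEP	1 PEP -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_PYR	1 PYR -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_ACCOA	1 ACCOA -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_OAA	1 OAA -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_AKG	1 AKG -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_DHAP	1 DHAP -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_ASP	1 ASP -> -	-	0	biomass_drain	0	0	0	BIOMASS
BM_SUCCOA	1 SUCCOA -> -	-	0	biomass_drain	0	0	0	BIOMASS
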