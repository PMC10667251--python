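# TCA-toy atom-transition network: lumped glycolysis, citric acid cycle with
# reductive IDH exchange, anaplerosis (PC), glutamine entry, GABA shunt and
# fixed biomass drains. Succinate and fumarate are rotationally symmetric.
#unbalanced	Glc.x Lac.x Gln.x Glu.x CO2.x SucDil.x PyrBM.x AcCoABM.x OAABM.x GluBM.x
#symmetric	Suc Fum
id	equation	reversible	lb	ub
GLC_up	Glc.x (abcdef) -> Pyr (cba) + Pyr (def)	0	0.0	100.0
LDH	Pyr (abc) -> Lac.x (abc)	1	-100.0	100.0
PDH	Pyr (abc) -> CO2.x (a) + AcCoA (bc)	0	0.0	100.0
PC	Pyr (abc) + CO2.x (d) -> OAA (abcd)	0	0.0	100.0
CS	AcCoA (ab) + OAA (cdef) -> Cit (fedbac)	0	0.0	100.0
IDH	Cit (abcdef) -> AKG (abcde) + CO2.x (f)	1	-100.0	100.0
OGDHC	AKG (abcde) -> Suc (bcde) + CO2.x (a)	0	0.0	100.0
SDH	Suc (abcd) -> Fum (abcd)	0	0.0	100.0
FH	Fum (abcd) -> Mal (abcd)	1	-100.0	100.0
MDH	Mal (abcd) -> OAA (abcd)	0	0.0	100.0
GDH	Glu (abcde) -> AKG (abcde)	1	-100.0	100.0
GLS	Gln (abcde) -> Glu (abcde)	0	0.0	100.0
GLN_up	Gln.x (abcde) -> Gln (abcde)	0	0.0	100.0
GLU_sec	Glu (abcde) -> Glu.x (abcde)	1	-100.0	100.0
GAD	Glu (abcde) -> GABA (bcde) + CO2.x (a)	0	0.0	100.0
GABAT	GABA (abcd) -> Suc (abcd)	0	0.0	100.0
SUC_dil	SucDil.x (abcd) -> Suc (abcd)	0	0.0	100.0
BM_Pyr	Pyr (abc) -> PyrBM.x (abc)	0	0.0	100.0
BM_AcCoA	AcCoA (ab) -> AcCoABM.x (ab)	0	0.0	100.0
BM_OAA	OAA (abcd) -> OAABM.x (abcd)	0	0.0	100.0
BM_Glu	Glu (abcde) -> GluBM.x (abcde)	0	0.0	100.0
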