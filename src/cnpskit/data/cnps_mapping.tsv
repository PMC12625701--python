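element	process_id	display_name	ko_id	gene_label
C	aerobic_carbon_fixation	Aerobic carbon fixation	K00855	prkB
C	aerobic_carbon_fixation	Aerobic carbon fixation	K01601	rbcL
C	aerobic_carbon_fixation	Aerobic carbon fixation	K01602	rbcS
C	anaerobic_carbon_fixation	Anaerobic carbon fixation	K00192	cdhA
C	anaerobic_carbon_fixation	Anaerobic carbon fixation	K00194	cdhD
C	anaerobic_carbon_fixation	Anaerobic carbon fixation	K00198	cooS
C	anaerobic_carbon_fixation	Anaerobic carbon fixation	K14138	acsB
C	aerobic_respiration	Aerobic respiration	K02274	coxA
C	aerobic_respiration	Aerobic respiration	K02275	coxB
C	aerobic_respiration	Aerobic respiration	K02276	coxC
C	fermentation	Fermentation	K00016	ldh
C	fermentation	Fermentation	K01568	pdc
C	fermentation	Fermentation	K00656	pflD
C	methanogenesis	Methanogenesis	K00399	mcrA
C	methanogenesis	Methanogenesis	K00401	mcrB
C	methanogenesis	Methanogenesis	K00402	mcrG
C	methane_oxidation	Methane oxidation	K10944	pmoA-amoA
C	methane_oxidation	Methane oxidation	K10945	pmoB-amoB
C	methane_oxidation	Methane oxidation	K10946	pmoC-amoC
C	co_oxidation	Carbon monoxide oxidation	K03518	coxS
C	co_oxidation	Carbon monoxide oxidation	K03519	coxM
C	co_oxidation	Carbon monoxide oxidation	K03520	coxL
N	nitrogen_fixation	Nitrogen fixation	K02586	nifD
N	nitrogen_fixation	Nitrogen fixation	K02588	nifH
N	nitrogen_fixation	Nitrogen fixation	K02591	nifK
N	ammonia_oxidation	Ammonia oxidation	K10944	pmoA-amoA
N	ammonia_oxidation	Ammonia oxidation	K10945	pmoB-amoB
N	ammonia_oxidation	Ammonia oxidation	K10946	pmoC-amoC
N	hydroxylamine_oxidation	Hydroxylamine oxidation	K10535	hao
N	nitrite_oxidation	Nitrite oxidation	K00370	nxrA
N	nitrite_oxidation	Nitrite oxidation	K00371	nxrB
N	dissimilatory_nitrate_reduction	Dissimilatory nitrate reduction	K02567	napA
N	dissimilatory_nitrate_reduction	Dissimilatory nitrate reduction	K02568	napB
N	denitrification_nitrite_reduction	Denitrification (nitrite reduction)	K00368	nirK
N	denitrification_nitrite_reduction	Denitrification (nitrite reduction)	K15864	nirS
N	nitric_oxide_reduction	Nitric oxide reduction	K04561	norB
N	nitric_oxide_reduction	Nitric oxide reduction	K02305	norC
N	nitrous_oxide_reduction	Nitrous oxide reduction	K00376	nosZ
N	dnra	Dissimilatory nitrite reduction to ammonium (DNRA)	K00362	nirB
N	dnra	Dissimilatory nitrite reduction to ammonium (DNRA)	K00363	nirD
N	dnra	Dissimilatory nitrite reduction to ammonium (DNRA)	K03385	nrfA
N	dnra	Dissimilatory nitrite reduction to ammonium (DNRA)	K15876	nrfH
N	assimilatory_nitrate_reduction	Assimilatory nitrate reduction	K00367	narB
N	assimilatory_nitrate_reduction	Assimilatory nitrate reduction	K10534	NR
N	assimilatory_nitrate_reduction	Assimilatory nitrate reduction	K00372	nasA
N	assimilatory_nitrate_reduction	Assimilatory nitrate reduction	K00360	nasB
N	assimilatory_nitrite_reduction	Assimilatory nitrite reduction	K00366	nirA
N	assimilatory_nitrite_reduction	Assimilatory nitrite reduction	K17877	NIT-6
N	anammox	Anaerobic ammonium oxidation (anammox)	K20932	hzsA
N	anammox	Anaerobic ammonium oxidation (anammox)	K20933	hzsB
N	anammox	Anaerobic ammonium oxidation (anammox)	K20934	hzsC
N	anammox	Anaerobic ammonium oxidation (anammox)	K20935	hdh
N	ammonium_uptake	Ammonium uptake	K03320	amt
N	nitrate_uptake	Nitrate uptake	K15576	nrtA
N	nitrate_uptake	Nitrate uptake	K15577	nrtB
N	nitrate_uptake	Nitrate uptake	K15578	nrtC
N	nitrate_uptake	Nitrate uptake	K15579	nrtD
N	nitrite_uptake	Nitrite uptake	K02575	narK
N	ureolysis	Ureolysis	K01427	ure
N	ureolysis	Ureolysis	K01428	ureC
N	ureolysis	Ureolysis	K01429	ureB
N	ureolysis	Ureolysis	K01430	ureA
N	ureolysis	Ureolysis	K14048	ureAB
N	nitrogen_assimilation	Ammonium assimilation	K01915	glnA
N	nitrogen_assimilation	Ammonium assimilation	K00265	gltB
N	nitrogen_assimilation	Ammonium assimilation	K00266	gltD
N	nitrogen_assimilation	Ammonium assimilation	K00260	gudB
N	nitrogen_assimilation	Ammonium assimilation	K00261	GLUD1_2
N	nitrogen_assimilation	Ammonium assimilation	K00262	gdhA
N	organic_nitrogen_mineralization	Organic nitrogen mineralization	K01455	formamidase
P	organic_p_mineralization	Organic phosphorus mineralization	K01077	phoA
P	organic_p_mineralization	Organic phosphorus mineralization	K01113	phoD
P	organic_p_mineralization	Organic phosphorus mineralization	K01126	glpQ
P	inorganic_p_solubilization	Inorganic phosphate solubilization	K00117	gcd
P	inorganic_p_solubilization	Inorganic phosphate solubilization	K01507	ppa
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00958	sat
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00955	cysNC
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00956	cysN
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00957	cysD
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00860	cysC
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00390	cysH
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00380	cysJ
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00381	cysI
S	assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00392	sir
S	aps_reduction	Dissimilatory APS reduction	K00394	aprA
S	aps_reduction	Dissimilatory APS reduction	K00395	aprB
S	dissimilatory_sulfite_reduction	Dissimilatory sulfite reduction	K11180	dsrA
S	dissimilatory_sulfite_reduction	Dissimilatory sulfite reduction	K11181	dsrB
S	dissimilatory_sulfite_reduction	Dissimilatory sulfite reduction	K11179	dsrC
S	sulfide_oxidation	Sulfide oxidation	K17218	sqr
S	sulfide_oxidation	Sulfide oxidation	K17229	fccA
S	sulfide_oxidation	Sulfide oxidation	K17230	fccB
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17222	soxA
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17223	soxX
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17224	soxB
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17225	soxC
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17226	soxY
S	thiosulfate_oxidation_sox	Thiosulfate oxidation (SOX complex)	K17227	soxZ
S	sulfite_oxidation	Sulfite oxidation	K00387	SUOX
S	sulfite_oxidation	Sulfite oxidation	K05301	sorA
S	sulfite_oxidation	Sulfite oxidation	K21307	soeA
S	thiosulfate_disproportionation	Thiosulfate disproportionation	K08352	phsA
S	thiosulfate_disproportionation	Thiosulfate disproportionation	K08353	phsB
S	thiosulfate_disproportionation	Thiosulfate disproportionation	K08354	phsC
S	sulfur_reduction	Elemental sulfur reduction	K17993	hydA
S	sulfur_reduction	Elemental sulfur reduction	K17996	hydG
S	sulfur_oxidation	Elemental sulfur oxidation	K17725	sdo
S	tetrathionate_reduction	Tetrathionate reduction	K08357	ttrA
S	tetrathionate_reduction	Tetrathionate reduction	K08358	ttrB
S	tetrathionate_reduction	Tetrathionate reduction	K08359	ttrC
S	tetrathionate_oxidation	Thiosulfate oxidation to tetrathionate	K19713	tsdA
S	tetrathionate_oxidation	Thiosulfate oxidation to tetrathionate	K16937	doxD
S	organic_sulfur_mineralization	Organic sulfur mineralization	K01130	aslA
S	organic_sulfur_mineralization	Organic sulfur mineralization	K01134	ARSA
S	dmsp_degradation	DMSP degradation	K17486	dmdA
S	dmsp_degradation	DMSP degradation	K16953	dddL
S	dmso_reduction	DMSO reduction	K07306	dmsA
S	dmso_reduction	DMSO reduction	K07307	dmsB
S	dmso_reduction	DMSO reduction	K07308	dmsC
S	taurine_utilization	Taurine utilization	K15551	tauA
S	taurine_utilization	Taurine utilization	K15552	tauB
S	taurine_utilization	Taurine utilization	K03119	tauD
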