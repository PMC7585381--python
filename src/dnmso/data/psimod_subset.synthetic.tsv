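accession	name	mono_delta	avg_delta	residues	terminus
MOD:00046	O-phospho-L-serine	79.966331	79.9799	S	none
MOD:00047	O-phospho-L-threonine	79.966331	79.9799	T	none
MOD:00048	O4'-phospho-L-tyrosine	79.966331	79.9799	Y	none
MOD:00719	L-methionine sulfoxide	15.994915	15.9994	M	none
MOD:00425	monohydroxylated residue	15.994915	15.9994	any	none
MOD:00394	acetylated residue	42.010565	42.0367	any	none
MOD:00064	N6-acetyl-L-lysine	42.010565	42.0367	K	none
MOD:00408	N-acetylated residue	42.010565	42.0367	any	N-term
MOD:00599	monomethylated L-lysine	14.015650	14.0266	K	none
MOD:00429	dimethylated residue	28.031300	28.0532	any	none
MOD:00430	trimethylated residue	42.046950	42.0797	any	none
MOD:01060	S-carboxamidomethyl-L-cysteine	57.021464	57.0513	C	none
MOD:00400	deamidated residue	0.984016	0.9848	NQ	none
MOD:00080	N4-deglycosylated-L-asparagine	0.984016	0.9848	N	none
MOD:00118	amidated residue	-0.984016	-0.9848	any	C-term
MOD:00040	2-pyrrolidone-5-carboxylic acid (Gln)	-17.026549	-17.0305	Q	N-term
MOD:00420	dehydrated residue	-18.010565	-18.0153	ST	none
MOD:00493	formylated residue	27.994915	28.0101	any	N-term
MOD:00440	carbamoylated residue	43.005814	43.0247	any	none
MOD:01352	nitrated residue	44.985078	44.9976	Y	none
MOD:00695	sulfated residue	79.956815	80.0632	Y	none
MOD:00448	myristoylated residue	210.198366	210.3556	any	N-term
MOD:00086	palmitoylated residue	238.229666	238.4136	C	none
MOD:00492	ubiquitinylation residue signature (GG)	114.042927	114.1026	K	none
MOD:00234	N-glycosyl-L-asparagine (HexNAc)	203.079373	203.1925	N	none
MOD:00675	oxidized residue	15.994915	15.9994	any	none
MOD:00412	dihydroxylated residue	31.989829	31.9988	any	none
MOD:00704	guanidinated residue	42.021798	42.0400	K	none
MOD:00359	phosphorylated residue	79.966331	79.9799	any	none
MOD:00000	protein modification (uncharacterized)	0.000000	0.0000	any	none
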