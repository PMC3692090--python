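# PTM reaction catalogue.
#
# The full upstream catalogue (256 reactions / 110 products)
# was not available for transcription; this table is a documented
# representative subset.  Counts therefore reflect THIS table, not the
# upstream tool's.  Entries without a template_id are names-layer only
# (catalogued but not executable).  Product codes marked (local) in the
# description are registry-local; the rest are wwPDB chemical-component codes.
#
# columns: reaction_id	target	terminus	product_code	template_id	description
phosphorylation	SER	-	SEP	phospho_ser	O-phosphorylation of serine
phosphorylation	THR	-	TPO	phospho_thr	O-phosphorylation of threonine
phosphorylation	TYR	-	PTR	phospho_tyr	O-phosphorylation of tyrosine
phosphorylation	HIS	-	NEP	-	N1-phosphorylation of histidine
phosphorylation	ASP	-	PHD	-	aspartyl phosphate
acetylation	LYS	-	ALY	acetyl_lys	N6-acetylation of lysine
acetylation	SER	-	OAS	-	O-acetylation of serine
acetylation	ALA	N	AYA	nterm_acetyl_ala	N-terminal acetylation (on Ala)
acetylation	GLY	N	GAC	-	N-terminal acetylation (on Gly) (local)
acetylation	MET	N	MAC	-	N-terminal acetylation (on Met) (local)
methylation	LYS	-	MLZ	methyl_lys	N6-monomethylation of lysine
methylation	MLZ	-	MLY	methyl_lys2	second N6-methylation (chained on monomethyllysine)
methylation	MLY	-	M3L	methyl_lys3	third N6-methylation (chained on dimethyllysine)
methylation	ARG	-	RME	methyl_arg	omega-N-methylation of arginine (local)
methylation	HIS	-	HIC	-	4-methylhistidine
methylation	GLU	-	MEG	-	glutamate methyl ester (local)
methylation	GLN	-	MGN	-	N5-methylglutamine (local)
dimethylation	LYS	-	MLY	dimethyl_lys	N6,N6-dimethylation of lysine
dimethylation	ARG	-	2MR	-	N-omega,N-omega-dimethylarginine
trimethylation	LYS	-	M3L	trimethyl_lys	N6,N6,N6-trimethylation of lysine
hydroxylation	PRO	-	HYP	hydroxy_pro	4-hydroxylation of proline
hydroxylation	LYS	-	LYZ	-	5-hydroxylysine
hydroxylation	ASN	-	AHB	-	beta-hydroxyasparagine
hydroxylation	ASP	-	BHD	-	beta-hydroxyaspartate
carboxylation	GLU	-	CGU	carboxy_glu	gamma-carboxylation of glutamate
nitration	TYR	-	NIY	nitro_tyr	3-nitration of tyrosine
carbonylation	LYS	-	KAS	carbonyl_lys	lysine to aminoadipic semialdehyde (allysine) (local)
carbonylation	ARG	-	RGS	carbonyl_arg	arginine to glutamic semialdehyde (local)
carbonylation	PRO	-	PGS	carbonyl_pro	proline to glutamic semialdehyde, ring-opened (local)
carbonylation	THR	-	TKB	carbonyl_thr	threonine to 2-amino-3-ketobutyrate (local)
deamidation	ASN	-	ASP	deamidate_asn	asparagine to aspartate
deamidation	GLN	-	GLU	deamidate_gln	glutamine to glutamate
amidation	ASP	-	ASN	amidate_asp	aspartate to asparagine (reverse of deamidation)
amidation	GLU	-	GLN	amidate_glu	glutamate to glutamine (reverse of deamidation)
oxidation	MET	-	SME	oxidize_met	methionine sulfoxide
oxidation	CYS	-	CSO	oxidize_cys	cysteine sulfenic acid
dioxidation	MET	-	OMT	-	methionine sulfone
dioxidation	CYS	-	CSD	-	cysteine sulfinic acid
trioxidation	CYS	-	OCS	-	cysteine sulfonic acid
sulfation	TYR	-	TYS	-	O-sulfotyrosine
nitrosylation	CYS	-	SNC	-	S-nitrosocysteine
palmitoylation	CYS	-	PMC	-	S-palmitoylcysteine (local)
citrullination	ARG	-	CIR	-	citrulline
carbamylation	LYS	-	HCI	-	homocitrulline (local)
formylation	LYS	-	FLY	-	N6-formyllysine (local)
succinylation	LYS	-	SLL	-	N6-succinyllysine (local)
oxidation	TRP	-	NFK	-	N-formylkynurenine (local)
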