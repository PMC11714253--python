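module_id	name	compartment	substrates	products	genes	group
M1	glucose uptake and phosphorylation	cytosol	GLC_e	G6P_c	SLC2A1;SLC2A2;SLC2A3;SLC2A4;SLC2A14;HK1;HK2;HK3;HKDC1;GCK	glycolysis
M2	G6P to glyceraldehyde-3-phosphate	cytosol	G6P_c	G3P_c	GPI;PFKL;PFKM;PFKP;PFKFB1;PFKFB2;PFKFB3;PFKFB4;FBP1;FBP2;ALDOA;ALDOB;ALDOC;TPI1	glycolysis
M3	G3P to 3-phosphoglycerate	cytosol	G3P_c	PG3_c	GAPDH;GAPDHS;PGK1;PGK2	glycolysis
M4	3PG to pyruvate	cytosol	PG3_c	PYR_c	PGAM1;PGAM2;PGAM4;BPGM;ENO1;ENO2;ENO3;ENO4;PKM;PKLR	glycolysis
M5	pyruvate to lactate and export	cytosol	PYR_c	LAC_e	LDHA;LDHB;LDHC;LDHD;LDHAL6A;LDHAL6B;SLC16A1;SLC16A3;SLC16A7;SLC16A8	glycolysis
M6	G6P to glycogen	cytosol	G6P_c	GLYCOGEN_c	PGM1;PGM2;UGP2;GYS1;GYS2;GBE1;GYG1;GYG2;PYGL;PYGB;PYGM;AGL;GSK3A;GSK3B	glycogen
M7	G3P to nucleotide synthesis	cytosol	G3P_c	NUCLEOTIDE_c	TKT;TKTL1;TKTL2;TALDO1;RPIA;RPE;PRPS1;PRPS2;PRPS1L1;PRPSAP1;PRPSAP2	branch_nucleotide
M8	3PG to serine synthesis	cytosol	PG3_c	SERINE_c	PHGDH;PSAT1;PSPH;SHMT1;SHMT2	branch_serine
M9	pyruvate to alanine	cytosol	PYR_c	ALANINE_c	GPT;GPT2	pyruvate_fate
M10	pyruvate import into mitochondria	mitochondrion	PYR_c	PYR_m	MPC1;MPC2	tca_upper
M11	pyruvate to acetyl-CoA (PDH)	mitochondrion	PYR_m	ACCOA_m	PDHA1;PDHA2;PDHB;DLAT;DLD;PDHX;PDK1;PDK2;PDK3;PDK4;PDP1;PDP2;PDPR	tca_upper
M12	pyruvate carboxylation to oxaloacetate	mitochondrion	PYR_m	OAA_m	PC	tca_upper
M13	citrate synthase	mitochondrion	ACCOA_m;OAA_m	CIT_m	CS	tca_upper
M14	citrate to 2-oxoglutarate	mitochondrion	CIT_m	OG2_m	ACO1;ACO2;IDH1;IDH2;IDH3A;IDH3B;IDH3G	tca_upper
M15	2-oxoglutarate to succinate	mitochondrion	OG2_m	SUC_m	OGDH;OGDHL;DLST;SUCLG1;SUCLG2;SUCLA2	tca_lower
M16	malic enzyme (malate to pyruvate)	mitochondrion	MAL_m	PYR_m	ME1;ME2;ME3	tca_lower
M17	succinate to fumarate	mitochondrion	SUC_m	FUM_m	SDHA;SDHB;SDHC;SDHD;SDHAF1;SDHAF2	tca_lower
M18	fumarate to malate	mitochondrion	FUM_m	MAL_m	FH	tca_lower
M19	malate to oxaloacetate	mitochondrion	MAL_m	OAA_m	MDH2	tca_lower
M20	citrate export and fatty-acid synthesis	cytosol	CIT_m	FATTY_ACID_c	SLC25A1;ACLY;ACSS2;ACACA;ACACB;FASN;MCAT;OXSM;ELOVL1;ELOVL2;ELOVL3;ELOVL4;ELOVL5;ELOVL6;ELOVL7;SCD;SCD5;ACSL1;ACSL3;ACSL4;ACSL5;ACSL6;AACS	lipogenesis
M21	oxaloacetate to cytosolic aspartate (shuttle out)	mitochondrion	OAA_m	ASP_c	GOT2;SLC25A12;SLC25A13	branch_asp_malate_shuttle
M22	aspartate to mitochondrial malate (shuttle return)	cytosol	ASP_c	MAL_m	GOT1;MDH1;MDH1B;SLC25A11	branch_asp_malate_shuttle
M23	aspartate to asparagine	cytosol	ASP_c	ASPARAGINE_c	ASNS	branch_asp_malate_shuttle
M24	glutamine uptake	extracellular	GLN_e	GLN_c	SLC1A5;SLC38A1;SLC38A2;SLC38A3;SLC38A4;SLC38A5;SLC38A7;SLC6A14;SLC6A19;SLC7A5;SLC7A6;SLC7A8;SLC3A2	glutamine_glutamate
M25	glutaminolysis (glutaminase)	cytosol	GLN_c	GLU_c;NH4_c	GLS;GLS2	glutaminolysis
M26	glutamine to nucleotide synthesis	cytosol	GLN_c	NUCLEOTIDE_c	PPAT;PFAS;GART;PAICS;ADSL;ADSSL1;ADSS;ATIC;IMPDH1;IMPDH2;GMPS;CAD;DHODH;UMPS;CTPS1;CTPS2;NME1;NME2;NME3;NME4;AK1;AK2;AK4;CMPK1;GUK1;UCK1;UCK2;ADK;HPRT1;APRT;TK1;RRM1;RRM2;RRM2B;TYMS;DTYMK	glutamine_glutamate
M27	glutamate to glutathione	cytosol	GLU_c;CYS_e;GLY_e	GSH_c	GCLC;GCLM;GSS	glutathione
M28	glutamate to 2-oxoglutarate	mitochondrion	GLU_c	OG2_m;NH4_c	GLUD1;GLUD2;SLC25A22;SLC25A18	glutamine_glutamate
M29	glutathione oxidation and conjugation	cytosol	GSH_c	GSSG_c	GPX1;GPX2;GPX3;GPX4;GPX5;GPX6;GPX7;GPX8;GSR;GSTA1;GSTA2;GSTA3;GSTA4;GSTA5;GSTM1;GSTM2;GSTM3;GSTM4;GSTM5;GSTP1;GSTT1;GSTT2;GSTT2B;GSTZ1;GSTO1;GSTO2;GSTK1;MGST1;MGST2;MGST3;GGT1;GGT5;GGT6;GGT7;GGCT;CHAC1;CHAC2;OPLAH	glutathione
M30	glutamate to proline	cytosol	GLU_c	PROLINE_c	ALDH18A1;PYCR1;PYCR2;PYCRL	glutamine_glutamate
M31	glutamate export (xCT antiporter)	extracellular	GLU_c	GLU_e	SLC7A11;SLC3A2	glutamine_glutamate
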