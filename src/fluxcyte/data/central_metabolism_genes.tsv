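module_id	gene
M1	SLC2A1
M1	SLC2A2
M1	SLC2A3
M1	SLC2A4
M1	SLC2A14
M1	HK1
M1	HK2
M1	HK3
M1	HKDC1
M1	GCK
M2	GPI
M2	PFKL
M2	PFKM
M2	PFKP
M2	PFKFB1
M2	PFKFB2
M2	PFKFB3
M2	PFKFB4
M2	FBP1
M2	FBP2
M2	ALDOA
M2	ALDOB
M2	ALDOC
M2	TPI1
M3	GAPDH
M3	GAPDHS
M3	PGK1
M3	PGK2
M4	PGAM1
M4	PGAM2
M4	PGAM4
M4	BPGM
M4	ENO1
M4	ENO2
M4	ENO3
M4	ENO4
M4	PKM
M4	PKLR
M5	LDHA
M5	LDHB
M5	LDHC
M5	LDHD
M5	LDHAL6A
M5	LDHAL6B
M5	SLC16A1
M5	SLC16A3
M5	SLC16A7
M5	SLC16A8
M6	PGM1
M6	PGM2
M6	UGP2
M6	GYS1
M6	GYS2
M6	GBE1
M6	GYG1
M6	GYG2
M6	PYGL
M6	PYGB
M6	PYGM
M6	AGL
M6	GSK3A
M6	GSK3B
M7	TKT
M7	TKTL1
M7	TKTL2
M7	TALDO1
M7	RPIA
M7	RPE
M7	PRPS1
M7	PRPS2
M7	PRPS1L1
M7	PRPSAP1
M7	PRPSAP2
M8	PHGDH
M8	PSAT1
M8	PSPH
M8	SHMT1
M8	SHMT2
M9	GPT
M9	GPT2
M10	MPC1
M10	MPC2
M11	PDHA1
M11	PDHA2
M11	PDHB
M11	DLAT
M11	DLD
M11	PDHX
M11	PDK1
M11	PDK2
M11	PDK3
M11	PDK4
M11	PDP1
M11	PDP2
M11	PDPR
M12	PC
M13	CS
M14	ACO1
M14	ACO2
M14	IDH1
M14	IDH2
M14	IDH3A
M14	IDH3B
M14	IDH3G
M15	OGDH
M15	OGDHL
M15	DLST
M15	SUCLG1
M15	SUCLG2
M15	SUCLA2
M16	ME1
M16	ME2
M16	ME3
M17	SDHA
M17	SDHB
M17	SDHC
M17	SDHD
M17	SDHAF1
M17	SDHAF2
M18	FH
M19	MDH2
M20	SLC25A1
M20	ACLY
M20	ACSS2
M20	ACACA
M20	ACACB
M20	FASN
M20	MCAT
M20	OXSM
M20	ELOVL1
M20	ELOVL2
M20	ELOVL3
M20	ELOVL4
M20	ELOVL5
M20	ELOVL6
M20	ELOVL7
M20	SCD
M20	SCD5
M20	ACSL1
M20	ACSL3
M20	ACSL4
M20	ACSL5
M20	ACSL6
M20	AACS
M21	GOT2
M21	SLC25A12
M21	SLC25A13
M22	GOT1
M22	MDH1
M22	MDH1B
M22	SLC25A11
M23	ASNS
M24	SLC1A5
M24	SLC38A1
M24	SLC38A2
M24	SLC38A3
M24	SLC38A4
M24	SLC38A5
M24	SLC38A7
M24	SLC6A14
M24	SLC6A19
M24	SLC7A5
M24	SLC7A6
M24	SLC7A8
M24	SLC3A2
M25	GLS
M25	GLS2
M26	PPAT
M26	PFAS
M26	GART
M26	PAICS
M26	ADSL
M26	ADSSL1
M26	ADSS
M26	ATIC
M26	IMPDH1
M26	IMPDH2
M26	GMPS
M26	CAD
M26	DHODH
M26	UMPS
M26	CTPS1
M26	CTPS2
M26	NME1
M26	NME2
M26	NME3
M26	NME4
M26	AK1
M26	AK2
M26	AK4
M26	CMPK1
M26	GUK1
M26	UCK1
M26	UCK2
M26	ADK
M26	HPRT1
M26	APRT
M26	TK1
M26	RRM1
M26	RRM2
M26	RRM2B
M26	TYMS
M26	DTYMK
M27	GCLC
M27	GCLM
M27	GSS
M28	GLUD1
M28	GLUD2
M28	SLC25A22
M28	SLC25A18
M29	GPX1
M29	GPX2
M29	GPX3
M29	GPX4
M29	GPX5
M29	GPX6
M29	GPX7
M29	GPX8
M29	GSR
M29	GSTA1
M29	GSTA2
M29	GSTA3
M29	GSTA4
M29	GSTA5
M29	GSTM1
M29	GSTM2
M29	GSTM3
M29	GSTM4
M29	GSTM5
M29	GSTP1
M29	GSTT1
M29	GSTT2
M29	GSTT2B
M29	GSTZ1
M29	GSTO1
M29	GSTO2
M29	GSTK1
M29	MGST1
M29	MGST2
M29	MGST3
M29	GGT1
M29	GGT5
M29	GGT6
M29	GGT7
M29	GGCT
M29	CHAC1
M29	CHAC2
M29	OPLAH
M30	ALDH18A1
M30	PYCR1
M30	PYCR2
M30	PYCRL
M31	SLC7A11
M31	SLC3A2
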