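pharmacokinetic	synthetic stand-in: drug metabolism and transport genes (n=28)	DPYD	UPB1	UPP1	UPP2	CDA	CES1	CES2	TYMP	ABCB1	ABCC1	ABCC2	ABCC3	ABCC4	ABCC5	ABCG2	SLC29A1	SLC29A2	SLC22A7	CYP2A6	CYP3A4	CYP3A5	CYP2C9	GSTP1	GSTM1	UGT1A1	NAT1	NAT2	SULT1A1
purine_pyrimidine_metabolism	synthetic stand-in: purine and pyrimidine metabolism genes (n=47)	TYMS	DHFR	RRM1	RRM2	RRM2B	POLA1	POLB	POLD1	POLE	PRPS1	PRPS2	PPAT	GART	PFAS	PAICS	ADSL	ADSS1	ADSS2	ATIC	IMPDH1	IMPDH2	GMPS	GUK1	ADK	APRT	HPRT1	XDH	PNP	NT5E	NT5C2	CAD	DHODH	UMPS	CMPK1	CTPS1	CTPS2	NME1	NME2	DUT	DCK	DCTD	TK1	TK2	AK1	AK2	ENTPD1	ITPA
fu_downstream_effectors	synthetic stand-in: downstream 5-FU effector genes in DNA repair, cell cycle arrest and apoptosis (n=17)	TP53	CDKN1A	BAX	BCL2	FAS	CASP3	CASP8	CASP9	MLH1	MSH2	MSH6	PMS2	CHEK1	CHEK2	ATM	ATR	MYC
radio_response	synthetic stand-in: radiation-response DNA-damage genes (n=21)	H2AX	MDC1	TP53BP1	BRCA1	BRCA2	RAD51	RAD50	MRE11	NBN	PRKDC	XRCC1	XRCC2	XRCC3	XRCC4	XRCC5	XRCC6	LIG1	LIG3	LIG4	ERCC1	ERCC2
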