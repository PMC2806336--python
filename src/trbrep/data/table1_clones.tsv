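clone_id	tissue	breed	accession	v_aa	ndn_aa	j_aa	d_gene	j_gene	c_gene	cdr3_len_aa
pSTMos.01	young_thymus	Moscia_Leccese	FM993913	ASSQ	A(GT)VI	SYEQYFGPGTKLTVV	TRBD1	TRBJ2.7	TRBC2	14
pSTMos.02	young_thymus	Moscia_Leccese	FM993914	ASSPT	NIAY	SYEQYFGPGTKLTVV		TRBJ2.7	TRBC2	14
pSTMos.03	young_thymus	Moscia_Leccese	FM993915	ASSQ	SD(G)	EQYFGPGTKLTVV	TRBD3	TRBJ2.7	TRBC3	10
pSTMos.04	young_thymus	Moscia_Leccese	FM993916	ASSP	PP(GQ)V	NTEVFFGKGTRLTVV	TRBD1	TRBJ1.1	TRBC1	14
pSTMos.05	young_thymus	Moscia_Leccese	FM993917	ASSQG	R(D)L	SNNPLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC3	14
pSTMos.06	young_thymus	Moscia_Leccese	FM993918	ASSQG	P	NTDPLYFGAGSKLTVL		TRBJ2.2	TRBC2	12
pSTMos.07	young_thymus	Moscia_Leccese	FM993919	ASSR	VGTME(GQ)I	YNSOLQFGIGTRLTVT	TRBD1	TRBJ1.6	TRBC1	18
pSTMos.08	young_thymus	Moscia_Leccese	FM993920	ASSPT	E(GLWGG)R	YEQYFGPGTKLTVV	TRBD2	TRBJ2.7	TRBC3	16
pSTMos.09	young_thymus	Moscia_Leccese	FM993921	ASSQE	AR(LG)AR	YFGAGTRLSVL	TRBD3	TRBJ3.3	TRBC3	12
pSTMos.11	young_thymus	Moscia_Leccese	FM993922	ASSR	TALRP(LGE)HAL	YGELHFGPGTRLTVL	TRBD2	TRBJ2.1	TRBC2	20
pSTMos.12	young_thymus	Moscia_Leccese	FM993923	ASSPT	PT	YDERHFGPGTRLTVL		TRBJ3.1	TRBC3	12
pSTMos.13	young_thymus	Moscia_Leccese	FM993924	ASSR	P(WGQG)D	GELHFGPGTRLTVL	TRBD3	TRBJ2.1	TRBC2	14
pSTMos.14	young_thymus	Moscia_Leccese	FM993925	ASS	G	SNNPLYFGGGTRLLVL		TRBJ2.3	TRBC2	10
pSTMos.17	young_thymus	Moscia_Leccese	FM993926	ASSQD	M(G)ASA	AQLYFGAGSKLTVL	TRBD3	TRBJ3.2	TRBC3	14
pSTMos.18	young_thymus	Moscia_Leccese	FM993927	ASSQE	(GA)DH	NPLYFGGGTRLLVL	TRBD3	TRBJ2.3	TRBC3	13
pSTMos.19	young_thymus	Moscia_Leccese	FM993928	ASSQ	W	SNQAQHFGHGTRLAVL		TRBJ1.5	TRBC1	11
pSTMos.20	young_thymus	Moscia_Leccese	FM993929	ASSPT	LR(G)IIPT	YEQYFGPGTKLTVV	TRBD1	TRBJ2.7	TRBC3	16
pSTMos.21	young_thymus	Moscia_Leccese	FM993930	ASS	RSR(WG)QD	SERYFGAGTRLTVT	TRBD3	TRBJ3.5	TRBC3	14
pSTMos.22	young_thymus	Moscia_Leccese	FM993931	ASSR	(WG)QD	SERYFGAGTRLTVT	TRBD3	TRBJ3.5	TRBC3	12
pSTMos.23	young_thymus	Moscia_Leccese	FM993932	ASSQ	APYG(TF)	SETQYFGPGTRLLVL	TRBD2	TRBJ3.4	TRBC3	15
pSTMos.25	young_thymus	Moscia_Leccese	FM993933	ASSPT	R(Q)GG	DPLYFGAGSKLTVL	TRBD1	TRBJ2.2	TRBC3	13
pSSAR.01	blood	Sarda_Ionica	FM993934	ASSQ	SRR(D)VS	QTQYFGPGTRLLVL	TRBD1	TRBJ2.5	TRBC2	14
pSSAR.02	blood	Sarda_Ionica	FM993935	ASSQG	HR(TA)K	NERLYFGNGTKLSVL	TRBD1	TRBJ1.4	TRBC1	15
pSSAR.04	blood	Sarda_Ionica	FM993936	ASSQ	(AGGW)AL	SETQYFGPGTRLLVL	TRBD3	TRBJ3.4	TRBC3	15
pSSAR.05	blood	Sarda_Ionica	FM993937	ASSK	LG(R)DILN	EQYFGPGTKLTVV	TRBD1	TRBJ2.7	TRBC3	14
pSSAR.07	blood	Sarda_Ionica	FM993938	ASSQD	S(GTA)D	ERLYFGNGTKLSVL	TRBD1	TRBJ1.4	TRBC1	14
pSSAR.08	blood	Sarda_Ionica	FM993939	ASS	(LG)	NERLYFGNGTKLSVL	TRBD3	TRBJ1.4	TRBC1	10
pSSAR.10	blood	Sarda_Ionica	FM993940	ASSL	DI(R)PN	GELHFGPGTRLTVL	TRBD2	TRBJ2.1	TRBC3	13
pSSAR.11	blood	Sarda_Ionica	FM993941	ASSP	K(RD)GY	NPLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC2	13
pSSAR.16	blood	Sarda_Ionica	FM993942	ASSQE	Q(Q)SRF	NNPLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC1	15
pSSAR.17	blood	Sarda_Ionica	FM993943	ASSQ	SRRD	SNQAQHFGHGTRLAIL		TRBJ1.5	TRBC1	14
pSSAR.19	blood	Sarda_Ionica	FM993944	ASSP	S(DFG)IG	NNPLYFGGGTRLLVL	TRBD2	TRBJ2.3	TRBC2	15
pSSAR.23	blood	Sarda_Ionica	FM993945	ASS	LSTVD	SQSTQYFGAGTRLSVL		TRBJ3.3	TRBC3	14
pSSAR.24	blood	Sarda_Ionica	FM993946	ASSQD	RKQGG	NSPLQFGIGTRLTVT		TRBJ1.6	TRBC1	15
pSSAR.25	blood	Sarda_Ionica	FM993947	ASS	FFST(G)E	ETQYFGPGTRLLVL	TRBD3	TRBJ3.4	TRBC3	13
pSSAR.28	blood	Sarda_Ionica	FM993948	ASSQ	(GQ)DRI	NPOLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC2	14
pSSAR.31	blood	Sarda_Ionica	FM993949	ASSP	DP(DSG)A	AQLYFGAGSKLTVL	TRBD1	TRBJ3.2	TRBC3	14
pSSAR.32	blood	Sarda_Ionica	FM993950	ASSQD	IS(QR)A	TDPLYFGAGSKLTVL	TRBD1	TRBJ2.2	TRBC3	15
pSMA.09	spleen	Gentile_di_Puglia	FM993951	ASSP	(LWGG)D	NPLYFGGGTRLLVL	TRBD2	TRBJ2.3	TRBC2	13
pSMA.10	spleen	Gentile_di_Puglia	FM993952	ASSQD	(AG)F	NPLYFGGGTRLLVL	TRBD3	TRBJ2.3	TRBC2	12
pSMA.41	spleen	Gentile_di_Puglia	FM993953	ASSQ	KR(TAG)	ERHFGPGTRLTVL	TRBD1	TRBJ3.1	TRBC3	12
pSMA.42	spleen	Gentile_di_Puglia	FM993954	ASS	L(GQRG)G	YEQYFGPGTKLTVV	TRBD1	TRBJ2.7	TRBC2	13
pSMA.46	spleen	Gentile_di_Puglia	FM993955	ASSQD	I	ETQYFGPGTRLLVL		TRBJ3.4	TRBC2	10
pSMA.48	spleen	Gentile_di_Puglia	FM993956	ASSQE	LT	YEQYFGPGTKLTVV		TRBJ2.7	TRBC3	11
pSMA.55	spleen	Gentile_di_Puglia	FM993957	ASSR	(DL)C	NNPLYFGGGTRLLVL	TRBD2	TRBJ2.3	TRBC3	12
pSMA.59	spleen	Gentile_di_Puglia	FM993958	ASSS	V(S)D	GELHFGPGTRLTVL	TRBD1	TRBJ2.1	TRBC2	11
pSMA.60	spleen	Gentile_di_Puglia	FM993959	ASSP	AV(G)SD	NPLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC3	13
pSMA.62	spleen	Gentile_di_Puglia	FM993960	ASSP	Q(TAG)E	DPLYFGAGSKLTVL	TRBD1	TRBJ2.2	TRBC2	13
pSMA.65	spleen	Gentile_di_Puglia	FM993961	ASSK	GR(TAG)P	SNNPLYFGGGTRLLVL	TRBD1	TRBJ2.3	TRBC3	16
pSMA.66	spleen	Gentile_di_Puglia	FM993962	ASSS	DR(GW)S	QTQYFGPGTRLLVL	TRBD3	TRBJ2.5	TRBC2	13
pSMA.67	spleen	Gentile_di_Puglia	FM993963	ASSK	TDF	YEQYFGPGTKLTVV		TRBJ2.7	TRBC2	11
pSMA.68	spleen	Gentile_di_Puglia	FM993964	ASS	W(T)LNA	AQLYFGAGSKLTVL	TRBD1	TRBJ3.2	TRBC2	12
pSMA.70	spleen	Gentile_di_Puglia	FM993965	ASSR	E(GTG)L	YEQYFGPGTKLTVV	TRBD1	TRBJ2.7	TRBC3	13
pSMA.71	spleen	Gentile_di_Puglia	FM993966	ASSP	(GP)T	NTEVFFGKGTRLTVV	TRBD1	TRBJ1.1	TRBC1	12
pSMA.73	spleen	Gentile_di_Puglia	FM993967	ASSP	FL(DS)V	DERHFGPGTRLTVL	TRBD1	TRBJ3.1	TRBC3	13
pSMA.74	spleen	Gentile_di_Puglia	FM993968	ASS	R(H)QNI	TDTQYFGPGTRLSVL	TRBD1	TRBJ2.4	TRBC2	13
pSMA.76	spleen	Gentile_di_Puglia	FM993969	ASSP	(S)	SNNPLYFGGGTRLLVL	TRBD3	TRBJ2.3	TRBC2	11
pSTA.01	adult_thymus	Gentile_di_Puglia	FM993970	ASSR	Y(SE)GD	EYHFGPGTKLTVV	TRBD1	TRBJ1.2	TRBC3	12
pSTA.02	adult_thymus	Gentile_di_Puglia	FM993971	ASSQD	LV(GTA)R	YEYHFGPGTKLTVV	TRBD1	TRBJ1.2	TRBC3	15
pSTA.03	adult_thymus	Gentile_di_Puglia	FM993972	ASS	FFST(G)E	ETQYFGPGTRLLVL	TRBD3	TRBJ3.4	TRBC3	13
pSTA.04	adult_thymus	Gentile_di_Puglia	FM993973	ASS	DS(W)DVQS	TQYFGPGTRLLVL	TRBD3	TRBJ3.4	TRBC3	13
pSTA.06	adult_thymus	Gentile_di_Puglia	FM993974	ASSQD	(R)D	YEYHFGPGTKLTVV	TRBD1	TRBJ1.2	TRBC3	11
pSTA.08	adult_thymus	Gentile_di_Puglia	FM993975	ASSP	S(R)D	TEVFFGKGTRLTVV	TRBD1	TRBJ1.1	TRBC3	11
pSTA.09	adult_thymus	Gentile_di_Puglia	FM993976	ASS	(LR)	ETQYFGPGTRLLVL	TRBD2	TRBJ3.4	TRBC3	9
pSTA.11	adult_thymus	Gentile_di_Puglia	FM993977	ASSP	(GQR)PP	DTQYFGPGTRLSVL	TRBD1	TRBJ2.4	TRBC2	13
pSTA.12	adult_thymus	Gentile_di_Puglia	FM993978	ASS	LS(GTRG)D	TQTQYFGPGTRLLVL	TRBD1	TRBJ2.5	TRBC2	15
pSTA.13	adult_thymus	Gentile_di_Puglia	FM993979	ASSR	K(RG)H	SETQYFGPGTRLLVL	TRBD1	TRBJ3.4	TRBC3	13
pSTA.15	adult_thymus	Gentile_di_Puglia	FM993980	ASS	IEKA	NPLYFGGGTRLLVL		TRBJ2.3	TRBC2	11
pSTA.24	adult_thymus	Gentile_di_Puglia	FM993981	ASSK	DL(AGG)VS	SETQYFGPGTRLLVL	TRBD3	TRBJ3.4	TRBC2	16
pSTA.25	adult_thymus	Gentile_di_Puglia	FM993982	ASSL	ER(QR)	DERHFGPGTRLTVL	TRBD1	TRBJ3.1	TRBC3	12
pSTA.26	adult_thymus	Gentile_di_Puglia	FM993983	ASSP	R(S)DK	GELHFGPGTRLTVL	TRBD1	TRBJ2.1	TRBC1	12
pSTA.29	adult_thymus	Gentile_di_Puglia	FM993984	ASSP	RQ(T)GPFG	EYHFGPGTKLTVV	TRBD1	TRBJ1.2	TRBC1	14
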