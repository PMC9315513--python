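event_id	gene5	gene3	strand5	strand3	chr5	pos5	chr3	pos3	annotation	own_samples	own_cohort	AML	T-ALL_Leucegene	T-ALL_COG	B-ALL	BLCA	BRCA	CESC	COAD	KIRC	LGG	LUAD	PRAD	SKCM	THCA	CEU_normal	normal_panel
cg01	LRRC61	ZBED6CL	+	+	7	150328742	7	150330107	-	#14	1/10	17/27	8/12	6/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	1/20	0/91	0/14
cg02	ZNF250	COMMD5	+	+	8	144880365	8	144851395	GenBank	#14	1/10	15/27	9/12	4/14	4/20	0/20	0/20	0/20	0/20	0/20	1/20	0/20	1/20	0/20	0/20	0/91	0/14
cg03	RP11-305L7.3	RP11-305L7.1	+	+	9	91163005	9	91106671	RefSeq	#13	1/10	10/27	8/12	3/14	1/20	1/20	1/20	0/20	0/20	0/20	0/20	0/20	0/20	1/20	0/20	0/91	0/14
cg04	RP11-556E13.1	RP11-346D6.6	+	+	10	52561006	10	52463332	-	#11	1/10	9/27	2/12	0/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	1/20	0/20	1/20	0/20	0/91	0/14
cg05	OPN4	LDB3	+	+	10	86666848	10	86668669	GenBank;RefSeq	#16	1/10	0/27	0/12	0/14	2/20	0/20	1/20	1/20	0/20	6/20	9/20	0/20	0/20	1/20	0/20	0/91	0/14
cg06	C14orf37	RP11-999E24.3	+	+	14	58003907	14	57994417	RefSeq	#13	1/10	2/27	0/12	0/14	0/20	0/20	0/20	0/20	0/20	1/20	1/20	0/20	0/20	0/20	0/20	0/91	0/14
cg07	RP11-1360M22.11	RP11-810K23.8	+	+	15	20012876	15	21019524	-	#13	1/10	5/27	3/12	4/14	0/20	0/20	0/20	0/20	0/20	1/20	1/20	0/20	0/20	0/20	0/20	0/91	0/14
cg08	IGF1R	RP11-35O15.2	+	+	15	98649675	15	98660230	GenBank	#6;#7	2/10	8/27	3/12	0/14	3/20	0/20	1/20	2/20	0/20	0/20	1/20	0/20	0/20	0/20	0/20	0/91	0/14
cg09	NHLRC4	PIGQ	+	+	16	568989	16	574066	Ensembl;UCSC;Vega;ConjoinG;FusionHub	#7;#8	2/10	12/27	7/12	6/14	10/20	0/20	2/20	0/20	2/20	1/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg10	MAPK3	GDPD3	+	+	16	30114203	16	30113437	-	#11	1/10	10/27	5/12	4/14	4/20	0/20	1/20	0/20	0/20	0/20	1/20	0/20	0/20	0/20	0/20	0/91	0/14
cg11	TRAPPC1	KCNAB3	+	+	17	7930527	17	7927826	ConjoinG;FusionHub	#11	1/10	0/27	1/12	2/14	0/20	0/20	0/20	2/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg12	CTB-26E19.1	COL23A1	+	+	5	178442931	5	178306919	-	#11	1/10	2/27	7/12	7/14	3/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg13	SURF1	MED22	+	+	9	133351836	9	133345252	-	#6;#7	2/10	1/27	2/12	0/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg14	SURF1	MED22	+	+	9	133351836	9	133346700	-	#13	1/10	6/27	4/12	0/14	1/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg15	CACUL1	RP11-427L15.2	+	+	10	118693702	10	118692438	-	#7;#11	2/10	3/27	1/12	0/14	1/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg16	TMEM86A	RP11-1081L13.4	+	+	11	18702116	11	18706818	-	#7	1/10	1/27	1/12	1/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg17	RP11-20D14.3	RIMKLB	+	+	12	8668831	12	8713811	-	#6;#7;#9;#8;#11;#12;#13;#15;#16	9/10	17/27	1/12	1/14	16/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg18	RP11-397H6.1	RP11-541G9.1	+	+	12	97033423	12	97185076	-	#13	1/10	0/27	0/12	0/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg19	CCPG1	PIGBOS1	+	+	15	55355634	15	55317867	-	#6;#13	2/10	14/27	2/12	6/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg20	AC019118.3	AC019118.2	+	+	2	3145547	2	2966675	-	#14;#16	2/10	0/27	1/12	0/14	4/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg21	RP11-87G24.3	RP11-87G24.6	+	+	17	76963893	17	76957657	-	#7;#8;#12;#13;#14;#16	6/10	3/27	9/12	6/14	6/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg22	KLHL22	SCARF2	+	+	22	20446443	22	20430557	Ensembl;UCSC;Vega;ConjoinG;FusionHub	#9;#12;#13;#15	4/10	14/27	8/12	5/14	4/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg23	PPP1R3F	LL0XNC01-7P3.1	+	+	X	49270873	X	49273514	GenBank	#7	1/10	2/27	0/12	0/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg24	MYNN	RP11-362K14.7	+	+	3	169786730	3	169793627	-	#8;#14	2/10	8/27	4/12	4/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
cg25	FAM200B	BST1	+	+	4	15687148	4	15711807	RefSeq	#13;#14	2/10	3/27	2/12	0/14	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/20	0/91	0/14
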