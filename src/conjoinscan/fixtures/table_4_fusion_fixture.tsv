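event_id	gene5	gene3	strand5	strand3	chr5	pos5	chr3	pos3	annotation	own_samples	own_cohort	AML	T-ALL_Leucegene	T-ALL_COG	B-ALL	CEU_normal	normal_panel
fus01	IK	FBXW2	+	-	5	140659164	9	120792947	-	#13	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus02	ZNF444	HLA-B	+	-	19	56160570	6	31355372	-	#9	1/10	1/27	3/12	0/14	0/20	0/91	0/14
fus03	PAX5	POM121C	+	+	9	36966549	7	75441583	-	#6	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus04	NFX1	DICER1	+	-	9	33290597	14	95141748	-	#9	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus05	DCAF8	ZNF836	-	-	1	160220067	19	52156511	-	#14	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus06	DMD	STAMBPL1	-	+	X	32216916	10	88893871	-	#13	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus07	SLFNL1	SMPD2	-	+	1	41022123	6	109441113	-	#16	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus08	RP11-148O21.2	ATG4B	-	+	8	11558702	2	241672559	-	#7	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus09	TMEM263	CD47	+	-	12	106971137	3	108055566	-	#11	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus10	INPP5A	SETD7	+	-	10	132607956	4	139548119	-	#7	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus11	ZC3H12D	RP11-445F6.2	-	+	6	149456666	6	139271659	-	#14	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus12	NUP214	ABL1	-	-	9	131230769	9	130854801	FusionHub;AtlasGeneticsOncology	#16	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus13	MAML2	FAT3	-	+	11	96091892	11	92352096	-	#15	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus14	MNT	CLUH	-	-	17	2400640	17	2704564	-	#9;#11	2/10	3/27	2/12	0/14	0/20	0/91	0/14
fus15	TSKS	ARRDC2	-	+	19	49746470	19	18007338	-	#11	1/10	0/27	0/12	0/14	0/20	0/91	0/14
fus16	MAEA	CTBP1	+	-	4	1289982	4	1238337	FusionHub;AtlasGeneticsOncology	#7;#12	2/10	9/27	3/12	6/14	2/20	0/91	0/14
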